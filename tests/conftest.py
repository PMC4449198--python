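import numpy as np
import pandas as pd
import pytest

from aviqtl.io_formats import Cross, GeneticMap
from aviqtl.simulate import (
    EqtlEffect,
    HotspotSpec,
    MediationEffect,
    QtlEffect,
    SimConfig,
    make_map,
    nearest_locus,
    simulate_dataset,
)


def tiny_map(markers):
    """markers: list of (marker, chrom, pos_cM [, pos_Mb])."""
    rows = []
    for m in markers:
        row = {"marker": m[0], "chrom": str(m[1]), "pos_cM": float(m[2])}
        if len(m) > 3:
            row["pos_Mb"] = float(m[3])
        rows.append(row)
    return GeneticMap(pd.DataFrame(rows))


def make_cross(gmap, geno_codes, phenotypes=None, covariates=None):
    """geno_codes: n x p array of 0/1/2/nan."""
    geno = np.asarray(geno_codes, dtype=float)
    ids = pd.Index([f"i{k + 1}" for k in range(len(geno))], name="id")
    geno = pd.DataFrame(geno, index=ids, columns=gmap.markers)
    pheno = pd.DataFrame(phenotypes or {}, index=ids)
    cov = pd.DataFrame(covariates or {}, index=ids)
    return Cross(gmap, geno, pheno, cov)


@pytest.fixture(scope="session")
def demo_config():
    gmap = make_map(SimConfig(n_markers=63, n_chromosomes=3, chrom_length_cM=100.0))
    q1 = nearest_locus(gmap, "1", 50.0)
    q2 = nearest_locus(gmap, "2", 30.0)
    hs = nearest_locus(gmap, "3", 60.0)
    return SimConfig(
        n_markers=63,
        n_chromosomes=3,
        n_individuals_final=250,
        pop_per_generation=80,
        seed=11,
        n_probesets=60,
        qtl_spec=[
            QtlEffect("1", q1, 0.55, 0.1, "bone_density"),
            QtlEffect("2", q2, 0.45, 0.0, "bone_density"),
        ],
        eqtl_spec=[
            EqtlEffect("cis_p1", "1", q1, 0.9, cis=True),
            EqtlEffect("trans_p1", "2", q2, 0.8, cis=False),
        ],
        hotspot_spec=[HotspotSpec("3", hs, n_targets=8)],
        mediation_spec=[MediationEffect("cis_p1", "bone_density", 0.4)],
        geno_missing_rate=0.01,
        pheno_missing_rate=0.01,
    )


@pytest.fixture(scope="session")
def demo_dataset(demo_config):
    return simulate_dataset(demo_config)
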