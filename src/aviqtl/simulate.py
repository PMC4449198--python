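"""Synthetic advanced-intercross generator.

Simulates a two-founder-line advanced intercross (default eight
generations, ~100 birds per breeding generation), with sex/batch/body-weight
and egg covariates, traits built from additive, dominance, epistatic and
expression-mediated components, and an expression matrix with local (cis)
effects, distal (trans) hotspot regulators and Gaussian noise.  A
ground-truth sidecar records every simulated effect for parameter-recovery
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genoprob import haldane_r
from .io_formats import Cross, ExpressionSet, GeneticMap


@dataclass
class QtlEffect:
    chrom: str
    pos_cM: float
    a: float  # additive effect (per founder-B allele count coded -1/0/1)
    d: float  # dominance deviation
    trait: str


@dataclass
class EpistasisEffect:
    chrom1: str
    pos1_cM: float
    chrom2: str
    pos2_cM: float
    effect: float  # coefficient of x1 * x2
    trait: str


@dataclass
class EqtlEffect:
    probeset: str
    chrom: str
    pos_cM: float
    effect: float
    cis: bool


@dataclass
class HotspotSpec:
    chrom: str
    pos_cM: float
    n_targets: int
    effect_mean: float = 0.8
    effect_sd: float = 0.2


@dataclass
class MediationEffect:
    probeset: str
    trait: str
    slope: float


@dataclass
class SimConfig:
    """Full description of one synthetic dataset; seed determines everything."""

    n_markers: int = 100
    n_chromosomes: int = 5
    chrom_length_cM: float = 100.0
    n_founder_pairs: int = 1
    generations: int = 8
    pop_per_generation: int = 100
    n_individuals_final: int = 456
    seed: int = 0
    qtl_spec: list[QtlEffect] = field(default_factory=list)
    epistasis_spec: list[EpistasisEffect] = field(default_factory=list)
    eqtl_spec: list[EqtlEffect] = field(default_factory=list)
    hotspot_spec: list[HotspotSpec] = field(default_factory=list)
    mediation_spec: list[MediationEffect] = field(default_factory=list)
    n_probesets: int = 200
    trait_noise_sd: dict = field(default_factory=dict)  # trait -> sd (default 1.0)
    probe_noise_sd: float = 1.0
    n_batches: int = 5
    body_weight_beta: dict = field(default_factory=dict)  # trait -> slope on weight
    sex_effect: dict = field(default_factory=dict)  # trait -> M-F shift
    geno_missing_rate: float = 0.02
    pheno_missing_rate: float = 0.02
    mb_per_cM: float = 0.3

    def __post_init__(self) -> None:
        if self.generations < 2:
            raise ValueError("generations must be >= 2 (F2 at minimum)")

    def traits(self) -> list[str]:
        names = [q.trait for q in self.qtl_spec] + [e.trait for e in self.epistasis_spec]
        names += [m.trait for m in self.mediation_spec]
        return list(dict.fromkeys(names)) or ["trait1"]


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset (positions, effects, targets)."""

    qtl: list[QtlEffect]
    epistasis: list[EpistasisEffect]
    eqtl: list[EqtlEffect]
    hotspot_targets: dict  # hotspot key -> list of probeset ids
    mediation: list[MediationEffect]
    trait_genetic_variance: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "qtl": [asdict(q) for q in self.qtl],
            "epistasis": [asdict(e) for e in self.epistasis],
            "eqtl": [asdict(e) for e in self.eqtl],
            "hotspot_targets": self.hotspot_targets,
            "mediation": [asdict(m) for m in self.mediation],
            "trait_genetic_variance": self.trait_genetic_variance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# map and meiosis


def make_map(config: SimConfig) -> GeneticMap:
    """Evenly spaced markers over equal-length chromosomes; physical
    positions at a constant Mb/cM ratio."""
    per_chrom = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per_chrom[: config.n_markers % config.n_chromosomes] += 1
    rows = []
    for c in range(config.n_chromosomes):
        k = int(per_chrom[c])
        pos = np.linspace(0.0, config.chrom_length_cM, k)
        for i, p in enumerate(pos):
            rows.append(
                {
                    "marker": f"m{c + 1}_{i + 1}",
                    "chrom": str(c + 1),
                    "pos_cM": float(p),
                    "pos_Mb": float(p * config.mb_per_cM),
                }
            )
    return GeneticMap(pd.DataFrame(rows))


def nearest_locus(gmap: GeneticMap, chrom: str, pos_cM: float) -> float:
    """Closest marker position on a chromosome (for building effect specs)."""
    tab = gmap.chrom_table(str(chrom))
    pos = tab["pos_cM"].to_numpy(dtype=float)
    return float(pos[np.argmin(np.abs(pos - pos_cM))])


def _meiosis(hap0: np.ndarray, hap1: np.ndarray, switch_p: np.ndarray, rng) -> np.ndarray:
    """One gamete from a parent's two haplotypes.

    ``switch_p`` holds the Haldane recombination fraction between
    consecutive markers (length p-1, with 0 at chromosome boundaries handled
    by the caller passing r = 0.5 there).
    """
    p = len(hap0)
    choose = np.empty(p, dtype=bool)
    choose[0] = rng.random() < 0.5
    flips = rng.random(p - 1) < switch_p
    choose[1:] = np.logical_xor.accumulate(flips) ^ choose[0]
    return np.where(choose, hap1, hap0)


def _switch_probs(gmap: GeneticMap) -> np.ndarray:
    """Per-interval recombination fractions; 0.5 across chromosome breaks."""
    tab = gmap.table
    pos = tab["pos_cM"].to_numpy(dtype=float)
    chrom = tab["chrom"].to_numpy()
    r = np.asarray(haldane_r(np.diff(pos)), dtype=float)
    r[chrom[1:] != chrom[:-1]] = 0.5
    return r


def simulate_ail(config: SimConfig) -> tuple[Cross, SimTruth, GeneticMap]:
    """Simulate the advanced intercross genotypes and covariates.

    Founders are fixed for alternate alleles at every marker (line-cross
    idealisation); meioses use Haldane's map function with no interference;
    each generation is produced by random mating with dam != sire.
    """
    rng = np.random.default_rng(config.seed)
    gmap = make_map(config)
    _validate_loci(config, gmap)
    p = len(gmap.table)
    switch = _switch_probs(gmap)

    # F1: all individuals carry one all-0 and one all-1 haplotype
    n_f1 = max(config.pop_per_generation, 2)
    pop = [(np.zeros(p, dtype=np.int8), np.ones(p, dtype=np.int8)) for _ in range(n_f1)]

    for gen in range(2, config.generations + 1):
        n_next = config.n_individuals_final if gen == config.generations else config.pop_per_generation
        new_pop = []
        for _ in range(n_next):
            dam, sire = rng.choice(len(pop), size=2, replace=False)
            g_d = _meiosis(*pop[dam], switch, rng)
            g_s = _meiosis(*pop[sire], switch, rng)
            new_pop.append((g_d, g_s))
        pop = new_pop

    geno_codes = np.array([h0 + h1 for h0, h1 in pop], dtype=float)  # 0/1/2

    n = len(pop)
    ids = pd.Index([f"ind{i + 1}" for i in range(n)], name="id")
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    batch = rng.integers(1, config.n_batches + 1, size=n)
    weight = rng.normal(1800.0, 150.0, size=n) + np.where(sex == "M", 400.0, 0.0)
    eggs = np.where(sex == "F", np.clip(rng.normal(10.0, 3.0, size=n), 0, None), np.nan)

    # missing-data injection
    if config.geno_missing_rate > 0:
        drop = rng.random(geno_codes.shape) < config.geno_missing_rate
        geno_codes[drop] = np.nan

    geno = pd.DataFrame(geno_codes, index=ids, columns=gmap.markers)
    covariates = pd.DataFrame(
        {
            "sex": sex,
            "batch": batch.astype(str),
            "body_weight": weight,
            "eggs": eggs,
        },
        index=ids,
    )
    phenotypes = pd.DataFrame(index=ids)
    cross = Cross(gmap, geno, phenotypes, covariates)
    truth = SimTruth(
        qtl=list(config.qtl_spec),
        epistasis=list(config.epistasis_spec),
        eqtl=list(config.eqtl_spec),
        hotspot_targets={},
        mediation=list(config.mediation_spec),
    )
    return cross, truth, gmap


def _validate_loci(config: SimConfig, gmap: GeneticMap) -> None:
    known = {
        (str(r["chrom"]), round(float(r["pos_cM"]), 6)) for _, r in gmap.table.iterrows()
    }

    def check(chrom, pos, what):
        if (str(chrom), round(float(pos), 6)) not in known:
            raise ValueError(f"{what} locus {chrom}:{pos} cM is not on the generated map")

    for q in config.qtl_spec:
        check(q.chrom, q.pos_cM, "QTL")
    for e in config.epistasis_spec:
        check(e.chrom1, e.pos1_cM, "epistasis")
        check(e.chrom2, e.pos2_cM, "epistasis")
    for e in config.eqtl_spec:
        check(e.chrom, e.pos_cM, "eQTL")
    for h in config.hotspot_spec:
        check(h.chrom, h.pos_cM, "hotspot")


def _marker_at(gmap: GeneticMap, chrom: str, pos_cM: float) -> str:
    tab = gmap.chrom_table(str(chrom))
    hits = tab[np.isclose(tab["pos_cM"], pos_cM)]
    if len(hits) == 0:
        raise KeyError(f"no marker at {chrom}:{pos_cM}")
    return str(hits["marker"].iloc[0])


def _xz(cross: Cross, chrom: str, pos_cM: float) -> tuple[np.ndarray, np.ndarray]:
    """Additive (-1/0/1) and dominance codes at a marker; missing -> 0."""
    marker = _marker_at(cross.gmap, chrom, pos_cM)
    g = cross.geno[marker].to_numpy(dtype=float)
    x = np.where(np.isnan(g), 0.0, g - 1.0)
    z = np.where(np.isnan(g), 0.0, (g == 1.0).astype(float))
    return x, z


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    cross: Cross,
    config: SimConfig,
    truth: SimTruth,
    individuals: pd.Index | None = None,
) -> ExpressionSet:
    """Expression matrix: baseline + cis effects + hotspot trans effects + noise.

    Cis probesets are annotated at their driving locus; hotspot target
    probesets are annotated on other chromosomes so their regulator is
    distal by construction.  Uses a seed derived from the config seed so the
    result is deterministic yet independent of the genotype stream.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    if individuals is None:
        individuals = cross.individuals
    sub = cross.subset(individuals)
    n = len(individuals)

    n_explicit = len(config.eqtl_spec)
    n_hotspot = sum(h.n_targets for h in config.hotspot_spec)
    if n_explicit + n_hotspot > config.n_probesets:
        raise ValueError(
            f"hotspot/eQTL targets ({n_explicit + n_hotspot}) exceed n_probesets "
            f"({config.n_probesets})"
        )

    chroms = cross.gmap.chromosomes
    probe_ids, ann_rows = [], []
    values = np.empty((config.n_probesets, n))
    eqtl_records: list[EqtlEffect] = list(config.eqtl_spec)
    hotspot_targets: dict[str, list[str]] = {}

    k = 0
    for e in config.eqtl_spec:
        x, _ = _xz(sub, e.chrom, e.pos_cM)
        baseline = rng.normal(8.0, 1.0)
        values[k] = baseline + e.effect * x + rng.normal(0, config.probe_noise_sd, n)
        if e.cis:
            ann_chrom, ann_cm = e.chrom, e.pos_cM
        else:
            ann_chrom = chroms[(chroms.index(str(e.chrom)) + 1) % len(chroms)]
            ann_cm = float(rng.uniform(0, cross.gmap.chrom_length(ann_chrom)))
        probe_ids.append(e.probeset)
        ann_rows.append((e.probeset, ann_chrom, ann_cm))
        k += 1

    for h_i, h in enumerate(config.hotspot_spec):
        x, _ = _xz(sub, h.chrom, h.pos_cM)
        key = f"{h.chrom}:{h.pos_cM}"
        hotspot_targets[key] = []
        for t in range(h.n_targets):
            pid = f"hs{h_i + 1}_t{t + 1}"
            eff = rng.normal(h.effect_mean, h.effect_sd) * (1 if rng.random() < 0.5 else -1)
            baseline = rng.normal(8.0, 1.0)
            values[k] = baseline + eff * x + rng.normal(0, config.probe_noise_sd, n)
            # annotate the target away from its regulator (distal by design)
            ann_chrom = chroms[(chroms.index(str(h.chrom)) + 1 + t % (len(chroms) - 1)) % len(chroms)] if len(chroms) > 1 else str(h.chrom)
            ann_cm = float(rng.uniform(0, cross.gmap.chrom_length(ann_chrom)))
            probe_ids.append(pid)
            ann_rows.append((pid, ann_chrom, ann_cm))
            eqtl_records.append(EqtlEffect(pid, h.chrom, h.pos_cM, float(eff), cis=False))
            hotspot_targets[key].append(pid)
            k += 1

    while k < config.n_probesets:
        pid = f"null_{k + 1}"
        ann_chrom = chroms[k % len(chroms)]
        ann_cm = float(rng.uniform(0, cross.gmap.chrom_length(ann_chrom)))
        values[k] = rng.normal(8.0, 1.0) + rng.normal(0, config.probe_noise_sd, n)
        probe_ids.append(pid)
        ann_rows.append((pid, ann_chrom, ann_cm))
        k += 1

    matrix = pd.DataFrame(values, index=pd.Index(probe_ids, name="probeset"), columns=individuals)
    ann = pd.DataFrame(
        {
            "chrom": [c for _, c, _ in ann_rows],
            "pos_cM": [p for _, _, p in ann_rows],
        },
        index=pd.Index([pid for pid, _, _ in ann_rows], name="probeset"),
    )
    ann["pos_Mb"] = ann["pos_cM"] * config.mb_per_cM
    truth.eqtl = eqtl_records
    truth.hotspot_targets = hotspot_targets
    return ExpressionSet(matrix=matrix, annotation=ann)


# ---------------------------------------------------------------------------
# traits


def simulate_traits(
    cross: Cross,
    config: SimConfig,
    truth: SimTruth,
    expr: ExpressionSet | None = None,
) -> Cross:
    """Add phenotype columns to the cross.

    trait = intercept + sex effect + batch effect + beta_w * weight
          + sum(a_i x_i + d_i z_i) + epistatic x_i x_j terms
          + mediated expression terms + Gaussian noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    n = cross.n_individuals
    sex_m = (cross.covariates["sex"] == "M").to_numpy(dtype=float)
    batches = cross.covariates["batch"].astype("category")
    batch_codes = batches.cat.codes.to_numpy()
    weight = cross.covariates["body_weight"].to_numpy(dtype=float)

    pheno = {}
    genetic_var = {}
    for trait in config.traits():
        noise_sd = float(config.trait_noise_sd.get(trait, 1.0))
        batch_eff = rng.normal(0, 0.25, size=batch_codes.max() + 1)
        y = (
            10.0
            + config.sex_effect.get(trait, 0.5) * sex_m
            + batch_eff[batch_codes]
            + config.body_weight_beta.get(trait, 0.001) * (weight - weight.mean())
        )
        g = np.zeros(n)
        for q in config.qtl_spec:
            if q.trait != trait:
                continue
            x, z = _xz(cross, q.chrom, q.pos_cM)
            g = g + q.a * x + q.d * z
        for e in config.epistasis_spec:
            if e.trait != trait:
                continue
            x1, _ = _xz(cross, e.chrom1, e.pos1_cM)
            x2, _ = _xz(cross, e.chrom2, e.pos2_cM)
            g = g + e.effect * x1 * x2
        for m in config.mediation_spec:
            if m.trait != trait:
                continue
            if expr is None:
                raise ValueError(
                    "mediation_spec requires the expression set (run simulate_expression first)"
                )
            ev = expr.matrix.loc[m.probeset]
            aligned = ev.reindex(cross.individuals)
            filled = aligned.fillna(aligned.mean()).to_numpy(dtype=float)
            g = g + m.slope * (filled - filled.mean())
        y = y + g
        if noise_sd > 0:
            y = y + rng.normal(0, noise_sd, n)
        genetic_var[trait] = float(np.var(g))
        pheno[trait] = y

    phenotypes = pd.DataFrame(pheno, index=cross.individuals)
    if config.pheno_missing_rate > 0:
        drop = rng.random(phenotypes.shape) < config.pheno_missing_rate
        phenotypes = phenotypes.mask(drop)
    truth.trait_genetic_variance = genetic_var
    return Cross(cross.gmap, cross.geno, phenotypes, cross.covariates)


def simulate_dataset(config: SimConfig) -> tuple[Cross, ExpressionSet, SimTruth]:
    """Convenience wrapper: genotypes, expression, traits, truth in one call."""
    cross, truth, _ = simulate_ail(config)
    expr = simulate_expression(cross, config, truth)
    cross = simulate_traits(cross, config, truth, expr=expr)
    return cross, expr, truth
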