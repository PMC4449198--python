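"""Conditional genotype probabilities for an F2-coded intercross.

A three-state hidden Markov chain runs along each chromosome with Haldane
transition probabilities; observed marker genotypes are emitted with an
optional genotyping-error rate.  Probabilities are computed at markers and
at pseudomarkers on a regular cM grid, and reduce to the additive dosage
``x = P(BB) - P(AA)`` and dominance indicator ``z = P(AB)`` used by
Haley-Knott regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Cross, GeneticMap

log = logging.getLogger(__name__)

#: F2 genotype prior (AA, AB, BB)
F2_PRIOR = np.array([0.25, 0.5, 0.25])


def haldane_r(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for distance d in cM (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM) / 100.0))


def haldane_d(r: float | np.ndarray) -> float | np.ndarray:
    """Inverse map function: distance in cM for recombination fraction r."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r))


def f2_transition(r: float) -> np.ndarray:
    """Transition matrix between F2 genotype states over one meiotic interval
    in each of the two gametes (rows: from AA/AB/BB)."""
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


@dataclass
class GenoProbs:
    """Genotype probabilities at markers and pseudomarkers.

    ``positions`` has columns ``chrom``, ``pos_cM``, ``name`` and
    ``is_marker``; ``probs`` is individuals x positions x 3 (AA, AB, BB).
    """

    positions: pd.DataFrame
    probs: np.ndarray
    individuals: pd.Index
    gmap: GeneticMap

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def x(self) -> np.ndarray:
        """Additive dosage P(BB) - P(AA), individuals x positions."""
        return self.probs[:, :, 2] - self.probs[:, :, 0]

    @property
    def z(self) -> np.ndarray:
        """Heterozygote probability, individuals x positions."""
        return self.probs[:, :, 1]

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.positions["chrom"].to_numpy() == chrom)

    def to_frame(self) -> pd.DataFrame:
        """Flat long-format table of the probabilities, for debugging."""
        n, p, _ = self.probs.shape
        rec = []
        for i, ind in enumerate(self.individuals):
            for j in range(p):
                rec.append(
                    (
                        ind,
                        self.positions["chrom"].iloc[j],
                        self.positions["pos_cM"].iloc[j],
                        self.positions["name"].iloc[j],
                        *self.probs[i, j],
                    )
                )
        return pd.DataFrame(rec, columns=["individual", "chrom", "pos_cM", "name", "pAA", "pAB", "pBB"])


def _position_grid(marker_pos: np.ndarray, step_cM: float) -> tuple[np.ndarray, np.ndarray]:
    """Marker positions merged with a regular pseudomarker grid.

    Returns (positions, is_marker).  With step 0 only markers are used.
    """
    if step_cM <= 0:
        return marker_pos.copy(), np.ones(len(marker_pos), dtype=bool)
    lo, hi = marker_pos[0], marker_pos[-1]
    grid = np.arange(lo, hi, step_cM)
    pos = np.concatenate([marker_pos, grid])
    is_marker = np.concatenate([np.ones(len(marker_pos), bool), np.zeros(len(grid), bool)])
    order = np.argsort(pos, kind="stable")
    pos, is_marker = pos[order], is_marker[order]
    # drop grid points that duplicate a marker position (within 1e-6 cM);
    # coincident markers are both kept
    keep = np.ones(len(pos), bool)
    for i in range(1, len(pos)):
        if pos[i] - pos[i - 1] < 1e-6:
            if not is_marker[i]:
                keep[i] = False
            elif not is_marker[i - 1]:
                keep[i - 1] = False
    return pos[keep], is_marker[keep]


def _emission(obs: np.ndarray, error_prob: float) -> np.ndarray:
    """Emission weights for observed codes (n,) with NaN = missing -> (n, 3)."""
    n = len(obs)
    em = np.ones((n, 3))
    typed = ~np.isnan(obs)
    if typed.any():
        codes = obs[typed].astype(int)
        block = np.full((typed.sum(), 3), error_prob / 2.0)
        block[np.arange(len(codes)), codes] = 1.0 - error_prob
        em[typed] = block
    return em


def calc_genoprob(cross: Cross, step_cM: float = 1.0, error_prob: float = 0.0) -> GenoProbs:
    """Forward-backward genotype probabilities along every chromosome.

    With ``error_prob = 0`` the probability triple at a typed marker is the
    indicator of the observed genotype.
    """
    if not (0.0 <= error_prob < 0.5):
        raise ValueError("error_prob must be in [0, 0.5)")
    if step_cM < 0:
        raise ValueError("step_cM must be >= 0")

    geno = cross.geno.to_numpy(dtype=float)
    n = len(geno)
    pos_frames, prob_blocks = [], []

    for chrom in cross.gmap.chromosomes:
        mtab = cross.gmap.chrom_table(chrom)
        if len(mtab) == 0:
            log.info("chromosome %s has no markers; skipped", chrom)
            continue
        marker_pos = mtab["pos_cM"].to_numpy(dtype=float)
        marker_idx = [cross.geno.columns.get_loc(m) for m in mtab["marker"]]
        obs = geno[:, marker_idx]  # n x n_markers_chr

        pos, is_marker = _position_grid(marker_pos, step_cM)
        p = len(pos)
        # emission per position: markers emit the observed genotype, grid = flat
        em = np.ones((n, p, 3))
        marker_slot = np.flatnonzero(is_marker)
        for k, j in enumerate(marker_slot):
            em[:, j, :] = _emission(obs[:, k], error_prob)

        trans = [f2_transition(float(haldane_r(pos[j + 1] - pos[j]))) for j in range(p - 1)]

        # scaled forward-backward, vectorised over individuals
        fwd = np.empty((p, n, 3))
        scale = np.empty((p, n))
        f = F2_PRIOR[None, :] * em[:, 0, :]
        scale[0] = f.sum(axis=1)
        fwd[0] = f / scale[0][:, None]
        for j in range(1, p):
            f = (fwd[j - 1] @ trans[j - 1]) * em[:, j, :]
            scale[j] = f.sum(axis=1)
            fwd[j] = f / scale[j][:, None]

        bwd = np.empty((p, n, 3))
        bwd[p - 1] = 1.0
        for j in range(p - 2, -1, -1):
            b = (bwd[j + 1] * em[:, j + 1, :]) @ trans[j].T
            bwd[j] = b / b.sum(axis=1)[:, None]

        post = fwd * bwd
        post /= post.sum(axis=2)[:, :, None]
        prob_blocks.append(np.transpose(post, (1, 0, 2)))

        names = []
        k = 0
        for j in range(p):
            if is_marker[j]:
                names.append(mtab["marker"].iloc[k])
                k += 1
            else:
                names.append(f"c{chrom}.loc{pos[j]:g}")
        pos_frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos_cM": pos, "name": names, "is_marker": is_marker}
            )
        )

    positions = pd.concat(pos_frames, ignore_index=True)
    probs = np.concatenate(prob_blocks, axis=1)
    return GenoProbs(positions=positions, probs=probs, individuals=cross.individuals, gmap=cross.gmap)


def map_expand(gmap: GeneticMap, factor: float) -> GeneticMap:
    """Multiply all cM positions by ``factor``.

    Used to approximate generation-k recombination when analysing
    advanced-intercross data with the F2 transition model.
    """
    return gmap.expand(factor)


def brute_force_genoprob(
    marker_pos: np.ndarray,
    obs: np.ndarray,
    query_pos: np.ndarray,
    error_prob: float = 0.0,
) -> np.ndarray:
    """Reference implementation by exhaustive hidden-sequence enumeration.

    For each query position, enumerates all 3^(m+1) genotype sequences over
    the markers plus that query, for a single individual.  Only usable for
    small marker counts; kept in the library so tests can assert oracle
    equivalence against the forward-backward path.
    """
    query_pos = np.asarray(query_pos, dtype=float)
    out = np.empty((len(query_pos), 3))
    for k, qp in enumerate(query_pos):
        out[k] = _brute_force_single(np.asarray(marker_pos, float), obs, np.array([qp]), error_prob)[0]
    return out


def _brute_force_single(
    marker_pos: np.ndarray,
    obs: np.ndarray,
    query_pos: np.ndarray,
    error_prob: float = 0.0,
) -> np.ndarray:
    pos = np.concatenate([marker_pos, query_pos])
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    kind = np.concatenate([np.arange(len(marker_pos)), np.full(len(query_pos), -1)])[order]
    p = len(pos)
    trans = [f2_transition(float(haldane_r(pos[j + 1] - pos[j]))) for j in range(p - 1)]
    em = np.ones((p, 3))
    for j in range(p):
        if kind[j] >= 0:
            em[j] = _emission(np.array([obs[kind[j]]]), error_prob)[0]

    post = np.zeros((p, 3))
    total = 0.0
    seq = np.zeros(p, dtype=int)

    def rec(j: int, prob: float) -> None:
        nonlocal total
        if j == p:
            total_here = prob
            nonlocal_post(seq, total_here)
            return
        for g in range(3):
            pr = prob * em[j, g]
            if j == 0:
                pr *= F2_PRIOR[g]
            else:
                pr *= trans[j - 1][seq[j - 1], g]
            if pr > 0:
                seq[j] = g
                rec(j + 1, pr)

    def nonlocal_post(seq: np.ndarray, pr: float) -> None:
        nonlocal total
        total += pr
        for j in range(p):
            post[j, seq[j]] += pr

    rec(0, 1.0)
    post /= total
    inv = np.argsort(order)
    return post[inv][len(marker_pos):]
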