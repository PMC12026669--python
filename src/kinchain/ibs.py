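"""Identity-by-state scoring.

Per locus, *ibs* is the size of the allele multiset intersection of the two
genotypes (0, 1 or 2; at most 1 when either genotype is hemizygous) and
*ibs0* flags loci sharing no allele.  Six aggregate scores summarize a pair:

* ``a_ibs``  = IBS_STR/(2·N_STR) + IBS_SNP/(2·N_SNP)  (range [0, 2])
* ``a_ibs0`` = IBS0_STR/N_STR + IBS0_SNP/N_SNP        (range [0, 2])
* ``x_ibs``, ``x_ibs0`` — raw sums over X loci, hemizygous males contributing
  single-allele genotypes
* ``y_ibs`` — count of Y loci with equal alleles; only defined for male–male
  pairs, otherwise missing
* ``m_ibs`` — 1 iff the two mtDNA haplotypes are identical
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

SCORE_COLUMNS = ["a_ibs", "a_ibs0", "x_ibs", "x_ibs0", "y_ibs", "m_ibs"]


@dataclass(frozen=True)
class IBSProfile:
    a_ibs: float
    a_ibs0: float
    x_ibs: int
    x_ibs0: int
    y_ibs: int | None       # None unless both individuals are male
    m_ibs: int
    pair_sexes: tuple[str, str]
    n_str: int
    n_snp: int


def ibs_locus(geno_a: Iterable[int], geno_b: Iterable[int]
              ) -> tuple[int, int]:
    """Per-locus (ibs, ibs0) for two allele multisets of size 1 or 2."""
    ca, cb = Counter(geno_a), Counter(geno_b)
    if not ca or not cb:
        raise ValueError("empty genotype")
    if sum(ca.values()) > 2 or sum(cb.values()) > 2:
        raise ValueError("genotypes carry at most two alleles per locus")
    shared = sum((ca & cb).values())
    return shared, int(shared == 0)


# ---------------------------------------------------------------------------
# vectorized kernels (arrays of shape (n, L[, ploidy]))

def _ibs_diploid(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(n, L, 2) vs (n, L, 2) -> per-locus ibs in {0, 1, 2}."""
    m1 = (a[..., 0] == b[..., 0]).astype(np.int8) + \
         (a[..., 1] == b[..., 1]).astype(np.int8)
    m2 = (a[..., 0] == b[..., 1]).astype(np.int8) + \
         (a[..., 1] == b[..., 0]).astype(np.int8)
    return np.maximum(m1, m2)


def _ibs_hemi_diploid(h: np.ndarray, d: np.ndarray) -> np.ndarray:
    """(n, L) vs (n, L, 2) -> per-locus ibs in {0, 1}."""
    return ((h == d[..., 0]) | (h == d[..., 1])).astype(np.int8)


def _ibs_hemi_hemi(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a == b).astype(np.int8)


def _x_ibs(batch_a, batch_b) -> np.ndarray:
    sa, sb = batch_a.sex, batch_b.sex
    if sa == "F" and sb == "F":
        return _ibs_diploid(batch_a.x, batch_b.x)
    if sa == "F":
        return _ibs_hemi_diploid(batch_b.x, batch_a.x)
    if sb == "F":
        return _ibs_hemi_diploid(batch_a.x, batch_b.x)
    return _ibs_hemi_hemi(batch_a.x, batch_b.x)


def score_batch(batch_a, batch_b, sim) -> pd.DataFrame:
    """Six IBS scores for paired replicate batches (same length).

    ``sim`` is the :class:`~kinchain.sim.PedigreeSimulator` whose panel the
    genotypes were drawn from (supplies locus order and STR/SNP masks).
    """
    is_str = sim.aut_is_str
    n_str = int(is_str.sum())
    n_snp = int((~is_str).sum())
    aut = _ibs_diploid(batch_a.aut, batch_b.aut)
    aut0 = (aut == 0)
    a_ibs = (aut[:, is_str].sum(1) / (2 * n_str)
             + aut[:, ~is_str].sum(1) / (2 * n_snp))
    a_ibs0 = (aut0[:, is_str].sum(1) / n_str
              + aut0[:, ~is_str].sum(1) / n_snp)
    x = _x_ibs(batch_a, batch_b)
    x_ibs = x.sum(1)
    x_ibs0 = (x == 0).sum(1)
    if batch_a.sex == "M" and batch_b.sex == "M":
        y_ibs = (batch_a.y == batch_b.y).sum(1).astype(float)
    else:
        y_ibs = np.full(len(aut), np.nan)
    m_ibs = (batch_a.mt == batch_b.mt).astype(int)
    return pd.DataFrame({
        "a_ibs": a_ibs, "a_ibs0": a_ibs0,
        "x_ibs": x_ibs, "x_ibs0": x_ibs0,
        "y_ibs": y_ibs, "m_ibs": m_ibs,
    })


def score_pair(pa, pb, panel) -> IBSProfile:
    """Six IBS scores for a single genotype pair over ``panel``."""
    aut_loci = panel.autosomal_loci()
    for geno, who in ((pa, "first"), (pb, "second")):
        missing = []
        if geno.autosomal.shape[1] != len(aut_loci):
            missing.append(f"autosomal ({geno.autosomal.shape[1]} of "
                           f"{len(aut_loci)} loci)")
        if geno.x.shape[1] != panel.n_x:
            missing.append(f"X ({geno.x.shape[1]} of {panel.n_x} loci)")
        if geno.sex == "M" and (geno.y is None or len(geno.y) != panel.n_y):
            missing.append(f"Y (expected {panel.n_y} loci)")
        if missing:
            raise ValueError(
                f"{who} genotype does not cover the panel: "
                + "; ".join(missing))

    is_str = np.array([l.kind == "STR" for l in aut_loci])
    n_str, n_snp = int(is_str.sum()), int((~is_str).sum())
    aut = np.array([ibs_locus(pa.autosomal[:, i], pb.autosomal[:, i])[0]
                    for i in range(len(aut_loci))])
    a_ibs = aut[is_str].sum() / (2 * n_str) + aut[~is_str].sum() / (2 * n_snp)
    a_ibs0 = ((aut[is_str] == 0).sum() / n_str
              + (aut[~is_str] == 0).sum() / n_snp)
    x = np.array([ibs_locus(pa.x[:, i], pb.x[:, i])[0]
                  for i in range(panel.n_x)])
    y_ibs = (int((pa.y == pb.y).sum())
             if pa.sex == "M" and pb.sex == "M" else None)
    return IBSProfile(
        a_ibs=float(a_ibs), a_ibs0=float(a_ibs0),
        x_ibs=int(x.sum()), x_ibs0=int((x == 0).sum()),
        y_ibs=y_ibs, m_ibs=int(pa.mt == pb.mt),
        pair_sexes=(pa.sex, pb.sex), n_str=n_str, n_snp=n_snp)


def profile_row(profile: IBSProfile) -> dict:
    """An IBSProfile as a score-table row (missing Y as NaN)."""
    return {
        "sexes": "".join(sorted(profile.pair_sexes)),
        "a_ibs": profile.a_ibs, "a_ibs0": profile.a_ibs0,
        "x_ibs": profile.x_ibs, "x_ibs0": profile.x_ibs0,
        "y_ibs": np.nan if profile.y_ibs is None else profile.y_ibs,
        "m_ibs": profile.m_ibs,
    }
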