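"""Pedigree simulation with recombination and mutation.

For a given kinship chain the minimal pedigree realizing it is instantiated
(adding unrelated spouse founders where a path person has an off-path
parent), founder genotypes are drawn from the panel frequencies under
Hardy–Weinberg and linkage equilibrium, and genotypes are transmitted down
the pedigree:

* autosomes and maternal X — recombinant gametes, crossovers sampled
  independently per marker interval with the Kosambi recombination fraction,
  then per-locus mutation (STR ±1 repeat at rate 0.002, SNP flip at 1e-8);
* paternal X — a father passes his X to daughters intact apart from
  per-locus STR mutation at 0.002;
* Y — father to son with per-locus mutation at 0.002;
* mtDNA — mother to child without mutation or heteroplasmy.

All replicates of one chain are simulated simultaneously as numpy arrays of
shape ``(n_reps, n_loci)``, which keeps a 90-chain × 1000-replicate dataset
in the tens of seconds on one core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ibs as ibs_mod
from .kc import KinshipChain, parse_kc, path_pedigree
from .panel import AlleleFrequencySet, Locus, MarkerPanel

STR_MUTATION_RATE = 0.002
SNP_MUTATION_RATE = 1e-8


def kosambi_rc(d_cm) -> float | np.ndarray:
    """Kosambi map function: genetic distance (cM) -> recombination fraction,
    r = ½·tanh(2d); r ≈ d for small d (in Morgans) and r → ½ as d → ∞."""
    d = np.asarray(d_cm, dtype=float)
    if (d < 0).any():
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if np.isscalar(d_cm) else r


@dataclass(frozen=True)
class GeneticMapView:
    """Ordered loci of one linkage group with inter-locus recombination
    fractions (``rc[i]`` between locus ``i`` and ``i+1``; chromosome breaks
    carry rc = 0.5)."""

    names: tuple[str, ...]
    chroms: tuple[str, ...]
    cm: np.ndarray
    rc: np.ndarray

    @classmethod
    def from_loci(cls, loci: list[Locus]) -> "GeneticMapView":
        names = tuple(l.name for l in loci)
        chroms = tuple(l.chrom for l in loci)
        cm = np.array([l.cm for l in loci])
        rc = np.empty(max(len(loci) - 1, 0))
        for i in range(len(loci) - 1):
            if chroms[i] != chroms[i + 1]:
                rc[i] = 0.5  # independent assortment across chromosomes
            else:
                rc[i] = kosambi_rc(cm[i + 1] - cm[i])
        return cls(names, chroms, cm, rc)


@dataclass
class GenomeGenotype:
    """One individual's multi-marker genotype.

    ``autosomal``: (2, L) phased haplotypes over the merged STR+SNP order;
    ``x``: (2, Lx) for females, (1, Lx) for males; ``y``: (Ly,) for males,
    None for females; ``mt``: haplotype string.
    """

    sex: str
    autosomal: np.ndarray
    x: np.ndarray
    y: np.ndarray | None
    mt: str


@dataclass
class _Batch:
    """Genotypes of n replicate copies of one individual."""
    sex: str
    aut: np.ndarray              # (n, L, 2)
    x: np.ndarray                # (n, Lx, 2) female | (n, Lx) male
    y: np.ndarray | None         # (n, Ly) male
    mt: np.ndarray               # (n,) pool haplotype ids


class PedigreeSimulator:
    """Simulates genotype pairs for kinship chains over a fixed panel."""

    def __init__(self, panel: MarkerPanel, freqs: AlleleFrequencySet,
                 str_mutation_rate: float = STR_MUTATION_RATE,
                 snp_mutation_rate: float = SNP_MUTATION_RATE):
        self.panel = panel
        self.freqs = freqs
        self.str_mu = str_mutation_rate
        self.snp_mu = snp_mutation_rate

        aut = panel.autosomal_loci()
        self.aut_map = GeneticMapView.from_loci(aut)
        self.aut_is_str = np.array([l.kind == "STR" for l in aut])
        self.x_map = GeneticMapView.from_loci(panel.x_loci())

        self._aut_alleles, self._aut_cum = _freq_matrix(aut, freqs)
        self._x_alleles, self._x_cum = _freq_matrix(panel.x_loci(), freqs)
        self._y_pool = freqs.y_haplotypes.astype(np.int16)
        self._y_cum = np.cumsum(freqs.y_weights)
        self._mt_cum = np.cumsum(freqs.mt_weights)
        # collapse identical pool haplotypes onto one id so that mtDNA
        # identity can be tested on ids
        _, self._mt_ids = np.unique(freqs.mt_haplotypes, return_inverse=True)

    # -- founders ----------------------------------------------------------

    def sample_founder_batch(self, sex: str, n: int,
                             rng: np.random.Generator) -> _Batch:
        aut = _sample_alleles(self._aut_alleles, self._aut_cum, (n, 2), rng)
        if sex == "F":
            x = _sample_alleles(self._x_alleles, self._x_cum, (n, 2), rng)
            y = None
        else:
            x = _sample_alleles(self._x_alleles, self._x_cum, (n, 1), rng)[..., 0]
            y = self._y_pool[np.searchsorted(self._y_cum, rng.random(n))]
        mt = self._mt_ids[np.searchsorted(self._mt_cum, rng.random(n))]
        return _Batch(sex, aut, x, y, mt)

    def sample_founder(self, sex: str, rng: np.random.Generator
                       ) -> GenomeGenotype:
        """Draw one founder genotype from the panel frequencies (HWE)."""
        return self._to_genotype(self.sample_founder_batch(sex, 1, rng), 0)

    # -- gametes -----------------------------------------------------------

    def _mutate(self, hap: np.ndarray, is_str: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
        if self.str_mu > 0:
            m = (rng.random(hap.shape) < self.str_mu) & is_str
            if m.any():
                hap = hap + np.where(m, rng.choice([-1, 1], size=hap.shape), 0
                                     ).astype(hap.dtype)
        if self.snp_mu > 0 and not is_str.all():
            m = (rng.random(hap.shape) < self.snp_mu) & ~is_str
            if m.any():
                hap = np.where(m, 3 - hap, hap)  # SNP alleles are 1/2
        return hap

    def make_gamete_batch(self, diplo: np.ndarray, gmap: GeneticMapView,
                          is_str: np.ndarray, rng: np.random.Generator
                          ) -> np.ndarray:
        """Recombinant gametes from phased diplotypes (n, L, 2) -> (n, L)."""
        n, L, _ = diplo.shape
        start = rng.integers(0, 2, size=(n, 1))
        if L > 1:
            switches = rng.random((n, L - 1)) < gmap.rc
            phase = (start + np.concatenate(
                [np.zeros((n, 1), dtype=int),
                 np.cumsum(switches, axis=1)], axis=1)) % 2
        else:
            phase = start
        hap = np.take_along_axis(diplo, phase[..., None], axis=2)[..., 0]
        return self._mutate(hap, is_str, rng)

    def make_gamete(self, parent: GenomeGenotype, which: str,
                    rng: np.random.Generator) -> np.ndarray:
        """One recombinant gamete from a single parent genotype.

        ``which`` is "autosomal" or "X"; an X gamete can only be formed from
        a female (a male X passes intact to daughters, outside this path).
        """
        if which == "autosomal":
            diplo = parent.autosomal.T[None, :, :]
            return self.make_gamete_batch(
                diplo, self.aut_map, self.aut_is_str, rng)[0]
        if which == "X":
            if parent.sex != "M":
                diplo = parent.x.T[None, :, :]
                return self.make_gamete_batch(
                    diplo, self.x_map,
                    np.ones(len(self.x_map.names), bool), rng)[0]
            raise ValueError(
                "X gametes are recombinant only in females; a male X passes "
                "intact to daughters")
        raise ValueError(f"unknown gamete type {which!r}")

    # -- transmission ------------------------------------------------------

    def _child_batch(self, sex: str, father: _Batch, mother: _Batch,
                     rng: np.random.Generator) -> _Batch:
        pat = self.make_gamete_batch(father.aut, self.aut_map,
                                     self.aut_is_str, rng)
        mat = self.make_gamete_batch(mother.aut, self.aut_map,
                                     self.aut_is_str, rng)
        aut = np.stack([pat, mat], axis=-1)
        x_str = np.ones(len(self.x_map.names), bool)
        x_mat = self.make_gamete_batch(mother.x, self.x_map, x_str, rng)
        if sex == "F":
            x_pat = self._mutate(father.x.copy(), x_str, rng)
            x = np.stack([x_pat, x_mat], axis=-1)
            y = None
        else:
            x = x_mat
            y = self._mutate(father.y.copy(),
                             np.ones(father.y.shape[1], bool), rng)
        return _Batch(sex, aut, x, y, mother.mt.copy())

    def simulate_kc_batch(self, kc: KinshipChain | str, n: int,
                          rng: np.random.Generator) -> tuple[_Batch, _Batch]:
        """Simulate n independent pedigrees of one chain; return the two
        endpoint individuals as replicate batches."""
        if isinstance(kc, str):
            kc = parse_kc(kc)
        ped = path_pedigree(kc)
        sex = dict(ped.sex)
        father = dict(ped.father)
        mother = dict(ped.mother)
        # complete the pedigree: a person with one on-path parent gets an
        # anonymous unrelated founder as the other parent
        next_id = max(sex) + 1
        for p in list(sex):
            if p in father and p not in mother:
                sex[next_id] = "F"
                mother[p] = next_id
                next_id += 1
            elif p in mother and p not in father:
                sex[next_id] = "M"
                father[p] = next_id
                next_id += 1

        geno: dict[int, _Batch] = {}
        pending = set(sex)
        while pending:
            ready = sorted(
                p for p in pending
                if (p not in father or father[p] in geno)
                and (p not in mother or mother[p] in geno))
            for p in ready:
                if p in father:
                    geno[p] = self._child_batch(
                        sex[p], geno[father[p]], geno[mother[p]], rng)
                else:
                    geno[p] = self.sample_founder_batch(sex[p], n, rng)
                pending.discard(p)
        a, b = ped.endpoints
        return geno[a], geno[b]

    def simulate_kc_pair(self, kc: KinshipChain | str,
                         rng: np.random.Generator
                         ) -> tuple[GenomeGenotype, GenomeGenotype]:
        """Simulate one genotype pair related by the given chain."""
        a, b = self.simulate_kc_batch(kc, 1, rng)
        return self._to_genotype(a, 0), self._to_genotype(b, 0)

    def _to_genotype(self, batch: _Batch, i: int) -> GenomeGenotype:
        mt_hap = self.freqs.mt_haplotypes[_first_pool_index(
            self._mt_ids, batch.mt[i])]
        if batch.sex == "F":
            x = batch.x[i].T
            y = None
        else:
            x = batch.x[i][None, :]
            y = batch.y[i].copy()
        return GenomeGenotype(batch.sex, batch.aut[i].T.copy(), x.copy(),
                              y, mt_hap)

    # -- datasets ----------------------------------------------------------

    def simulate_dataset(self, kcs: list[str] | None, n_reps: int,
                         seed: int | np.random.Generator) -> pd.DataFrame:
        """IBS score table for ``n_reps`` simulated pairs of every chain.

        Columns: kc, replicate, sexes, a_ibs, a_ibs0, x_ibs, x_ibs0,
        y_ibs (NaN unless male–male), m_ibs.
        """
        from .kc import enumerate_kcs
        if n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        kcs = kcs if kcs is not None else enumerate_kcs()
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        frames = []
        for s in kcs:
            chain = parse_kc(s)
            a, b = self.simulate_kc_batch(chain, n_reps, rng)
            df = ibs_mod.score_batch(a, b, self)
            df.insert(0, "kc", str(chain))
            df.insert(1, "replicate", np.arange(n_reps))
            df.insert(2, "sexes", "".join(sorted(chain.endpoint_sexes)))
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _freq_matrix(loci: list[Locus], freqs: AlleleFrequencySet
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pad per-locus allele/frequency vectors into (L, K) matrices with a
    cumulative-frequency matrix for vectorized inverse-CDF sampling."""
    K = max(len(freqs.alleles[l.name]) for l in loci)
    A = np.zeros((len(loci), K), dtype=np.int16)
    C = np.ones((len(loci), K))
    for i, l in enumerate(loci):
        a, f = freqs.alleles[l.name], freqs.freqs[l.name]
        A[i, :len(a)] = a
        A[i, len(a):] = a[-1]
        C[i, :len(f)] = np.cumsum(f)
        C[i, -1] = 1.0 + 1e-12
    return A, C


def _sample_alleles(A: np.ndarray, C: np.ndarray, shape: tuple[int, ...],
                    rng: np.random.Generator) -> np.ndarray:
    """Draw alleles i.i.d. per locus: result shape = shape[:-1]+(L,)+(shape[-1],)
    collapsed as (n, L, ploidy) or (n, L) for ploidy handling by caller."""
    n, ploidy = shape
    L = A.shape[0]
    u = rng.random((n, ploidy, L, 1))
    idx = (u > C[None, None, :, :]).sum(axis=-1)
    out = np.take_along_axis(
        np.broadcast_to(A, (n, ploidy, L, A.shape[1])), idx[..., None],
        axis=-1)[..., 0]
    return np.moveaxis(out, 1, 2)  # (n, L, ploidy)


def _first_pool_index(ids: np.ndarray, target: int) -> int:
    return int(np.nonzero(ids == target)[0][0])


# ---------------------------------------------------------------------------
# genotype tables

def mt_variant_string(mt: str) -> str:
    """Render a synthetic mtDNA bit-haplotype as a comma-joined variant list
    ("." when no derived variants); arbitrary user strings pass through."""
    if mt and set(mt) <= {"0", "1"}:
        sites = [f"s{i + 1}" for i, b in enumerate(mt) if b == "1"]
        return ",".join(sites) if sites else "."
    return mt


def write_genotypes_tsv(genotypes: dict[str, GenomeGenotype],
                        panel: MarkerPanel, path: str,
                        metadata: dict | None = None) -> None:
    """One row per individual: sample, sex, then per-locus genotypes
    ("a/b" diploid, "a" hemizygous) and the mtDNA haplotype string."""
    aut = panel.autosomal_loci()
    xs = panel.x_loci()
    cols = [l.name for l in aut] + [l.name for l in xs] \
        + [l.name for l in panel.y_strs] + [panel.mt.name]
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("sample\tsex\t" + "\t".join(cols) + "\n")
        for name, g in genotypes.items():
            row = [name, g.sex]
            row += [f"{g.autosomal[0, i]}/{g.autosomal[1, i]}"
                    for i in range(len(aut))]
            if g.sex == "F":
                row += [f"{g.x[0, i]}/{g.x[1, i]}" for i in range(len(xs))]
            else:
                row += [str(g.x[0, i]) for i in range(len(xs))]
            if g.y is not None:
                row += [str(a) for a in g.y]
            else:
                row += ["."] * panel.n_y
            row.append(mt_variant_string(g.mt))
            fh.write("\t".join(row) + "\n")


def read_genotypes_tsv(path: str, panel: MarkerPanel
                       ) -> dict[str, GenomeGenotype]:
    """Parse a genotype table written by :func:`write_genotypes_tsv` (or
    hand-prepared in the same layout) into panel-aligned genotypes."""
    aut = panel.autosomal_loci()
    xs = panel.x_loci()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    expected = (["sample", "sex"] + [l.name for l in aut]
                + [l.name for l in xs] + [l.name for l in panel.y_strs]
                + [panel.mt.name])
    if header != expected:
        raise ValueError("genotype table columns do not match the panel")
    out: dict[str, GenomeGenotype] = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        name, sex = fields[0], fields[1]
        vals = fields[2:]
        a = np.array([[int(x) for x in v.split("/")]
                      for v in vals[:len(aut)]]).T
        xv = vals[len(aut):len(aut) + len(xs)]
        if sex == "F":
            x = np.array([[int(t) for t in v.split("/")] for v in xv]).T
        else:
            x = np.array([[int(v) for v in xv]])
        yv = vals[len(aut) + len(xs):len(aut) + len(xs) + panel.n_y]
        y = None if sex == "F" else np.array([int(v) for v in yv])
        out[name] = GenomeGenotype(sex, a, x, y, vals[-1])
    return out
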