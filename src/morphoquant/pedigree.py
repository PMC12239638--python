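"""Pedigree handling, the additive (numerator) relationship matrix, and
genotype utilities for biallelic life-history loci.

The two loci modelled throughout the package (*vgll3* and *six6*) are
biallelic with alleles E (early maturation) and L (late maturation).
Genotypes are coded additively as the count of L alleles: 0, 1, 2 for
EE, EL and LL, so a unit change in the code is one allelic substitution
from E to L.

The additive relationship matrix A holds expected additive relatedness
between all pedigree members (parent-offspring 0.5, full sibs 0.5,
self 1 + F) and is the covariance structure of the animal random effect
in the mixed models of :mod:`morphoquant.animal`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Pedigree",
    "RelationshipMatrix",
    "encode_additive_genotype",
    "decode_additive_genotype",
    "allele_frequencies",
    "additive_relationship_matrix",
    "gene_drop_relatedness",
    "read_pedigree_csv",
    "read_genotypes_csv",
]

_GENOTYPE_CODES = {"EE": 0, "EL": 1, "LE": 1, "LL": 2}


class PedigreeError(ValueError):
    """Raised for cyclic pedigrees or malformed pedigree records."""


def encode_additive_genotype(genotype: str | int) -> int:
    """Return the additive code (count of L alleles) for a genotype.

    Accepts two-letter strings over {E, L} in either order ("EL" == "LE")
    or an already-encoded integer in {0, 1, 2}.
    """
    if isinstance(genotype, (int, np.integer)) and not isinstance(genotype, bool):
        if genotype in (0, 1, 2):
            return int(genotype)
        raise ValueError(f"invalid additive genotype code: {genotype!r}")
    if isinstance(genotype, str):
        code = _GENOTYPE_CODES.get(genotype.strip().upper())
        if code is not None:
            return code
        # allow "0"/"1"/"2" in CSV cells
        s = genotype.strip()
        if s in ("0", "1", "2"):
            return int(s)
    raise ValueError(f"invalid genotype {genotype!r}: expected EE/EL/LE/LL or 0/1/2")


def decode_additive_genotype(code: int) -> str:
    """Inverse of :func:`encode_additive_genotype` (heterozygote -> 'EL')."""
    try:
        return {0: "EE", 1: "EL", 2: "LL"}[int(code)]
    except KeyError:
        raise ValueError(f"invalid additive genotype code: {code!r}") from None


def allele_frequencies(codes) -> tuple[float, float]:
    """Frequencies (freq_E, freq_L) from additive codes.

    freq_L is the fraction of L alleles among the 2n alleles carried by
    the n genotyped individuals; freq_E = 1 - freq_L.
    """
    arr = np.asarray(list(codes), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute allele frequencies from an empty list")
    if not np.all(np.isin(arr, (0.0, 1.0, 2.0))):
        raise ValueError("additive codes must be in {0, 1, 2}")
    freq_l = float(arr.sum() / (2 * arr.size))
    return 1.0 - freq_l, freq_l


@dataclass
class Pedigree:
    """Ordered pedigree records (individual, sire, dam).

    ``None`` marks an unknown parent; unknown parents are treated as
    unrelated, non-inbred founders. Records need not arrive in
    topological order; :meth:`toposorted` derives one and raises
    :class:`PedigreeError` on cycles.
    """

    records: list[tuple[str, str | None, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for ind, sire, dam in self.records:
            if ind in seen:
                raise PedigreeError(f"duplicate individual record: {ind!r}")
            if ind == sire or ind == dam:
                raise PedigreeError(f"individual {ind!r} is its own parent")
            seen.add(ind)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def parents(self) -> dict[str, tuple[str | None, str | None]]:
        return {ind: (sire, dam) for ind, sire, dam in self.records}

    def toposorted(self) -> "Pedigree":
        """Return an equivalent pedigree with parents before offspring.

        Parent tokens that never appear as an individual record are
        appended as founder records (logged), matching the convention
        that unknown ancestry means unrelated founders.
        """
        parent_map = self.parents()
        known = set(parent_map)
        implicit: list[str] = []
        for sire, dam in parent_map.values():
            for p in (sire, dam):
                if p is not None and p not in known and p not in implicit:
                    implicit.append(p)
        if implicit:
            logger.info(
                "pedigree: %d parent token(s) without own records treated as "
                "founders: %s", len(implicit), ", ".join(map(str, implicit[:10]))
            )
        order: list[str] = list(implicit)
        placed = set(implicit)
        pending = [r for r in self.records]
        # Kahn-style repeated sweep; cycle if a full pass places nothing.
        while pending:
            progressed = False
            still = []
            for ind, sire, dam in pending:
                if (sire is None or sire in placed) and (dam is None or dam in placed):
                    order.append(ind)
                    placed.add(ind)
                    progressed = True
                else:
                    still.append((ind, sire, dam))
            if not progressed:
                cyc = ", ".join(r[0] for r in still[:5])
                raise PedigreeError(f"cyclic pedigree (individuals involved: {cyc})")
            pending = still
        parent_map = self.parents()
        recs = [
            (i, *(parent_map.get(i, (None, None)))) for i in order
        ]
        return Pedigree(recs)


@dataclass
class RelationshipMatrix:
    """Expected additive relatedness between pedigree members."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match id count")

    def index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}

    def submatrix(self, ids) -> np.ndarray:
        idx = self.index()
        sel = np.array([idx[i] for i in ids])
        return self.values[np.ix_(sel, sel)]

    def loc(self, a: str, b: str) -> float:
        idx = self.index()
        return float(self.values[idx[a], idx[b]])


def additive_relationship_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular recursion.

    With individuals in topological order, A_ii = 1 + 0.5 * A_{s,d}
    (inbreeding from the parents' relatedness) and, for j earlier than i,
    A_ij = 0.5 * (A_{j,s} + A_{j,d}); unknown parents contribute zero.
    Founders are assumed unrelated and non-inbred.
    """
    ordered = pedigree.toposorted()
    ids = ordered.ids
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    parent_map = ordered.parents()
    for i, ind in enumerate(ids):
        sire, dam = parent_map.get(ind, (None, None))
        si = idx[sire] if sire is not None else None
        di = idx[dam] if dam is not None else None
        for j in range(i):
            a = 0.0
            if si is not None:
                a += A[j, si]
            if di is not None:
                a += A[j, di]
            A[i, j] = A[j, i] = 0.5 * a
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    # restore caller order
    perm = np.array([idx[i] for i in pedigree.ids])
    return RelationshipMatrix(list(pedigree.ids), A[np.ix_(perm, perm)])


def gene_drop_relatedness(
    pedigree: Pedigree, n_drops: int = 100_000, seed: int = 0
) -> tuple[RelationshipMatrix, np.ndarray]:
    """Monte-Carlo relatedness by gene dropping, with standard errors.

    Two distinct neutral alleles are seeded in every founder and dropped
    through the pedigree by Mendelian sampling, ``n_drops`` times in
    parallel. The realised relatedness between i and j in one drop is
    twice the probability that a random allele from i matches (is IBD
    to) a random allele from j, estimated by allele-pair identity.

    Serves as an independent simulation-based oracle for
    :func:`additive_relationship_matrix`; returns (matrix of MC means,
    matrix of MC standard errors of those means).
    """
    ordered = pedigree.toposorted()
    ids = ordered.ids
    idx = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    rng = np.random.default_rng(seed)
    # alleles[k, r, 0/1]: the two allele labels of individual k in drop r
    alleles = np.zeros((n, n_drops, 2), dtype=np.int64)
    parent_map = ordered.parents()
    next_label = 0
    for k, ind in enumerate(ids):
        sire, dam = parent_map.get(ind, (None, None))
        for slot, par in enumerate((sire, dam)):
            if par is None:
                alleles[k, :, slot] = next_label
                next_label += 1
            else:
                pick = rng.integers(0, 2, size=n_drops)
                alleles[k, :, slot] = alleles[idx[par], np.arange(n_drops), pick]
    A_mean = np.zeros((n, n))
    A_se = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            # P(random allele of i IBD to random allele of j), per drop
            eq = (
                alleles[i, :, :, None] == alleles[j, :, None, :]
            ).mean(axis=(1, 2))
            r = 2.0 * eq
            if i == j:
                # a_ii = 1 + F; self-comparison counts each allele
                # against itself, giving 2*(2 + 2*1[ibd])/4 = 1 + 1[ibd]
                pass
            A_mean[i, j] = A_mean[j, i] = r.mean()
            A_se[i, j] = A_se[j, i] = r.std(ddof=1) / np.sqrt(n_drops)
    perm = np.array([idx[i] for i in pedigree.ids])
    return (
        RelationshipMatrix(list(pedigree.ids), A_mean[np.ix_(perm, perm)]),
        A_se[np.ix_(perm, perm)],
    )


def read_pedigree_csv(path) -> Pedigree:
    """Read a 3-column pedigree CSV (header ``id,sire,dam``; empty = unknown)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree CSV must have columns {sorted(required)}")
    recs = [
        (row["id"], row["sire"] or None, row["dam"] or None)
        for _, row in df.iterrows()
    ]
    return Pedigree(recs)


def read_genotypes_csv(path) -> pd.DataFrame:
    """Read a genotype CSV (``id,vgll3,six6,sex``); genotypes may be
    letter pairs (EE/EL/LE/LL) or additive codes; missing cells stay NaN."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "vgll3", "six6", "sex"}
    if not required.issubset(df.columns):
        raise ValueError(f"genotype CSV must have columns {sorted(required)}")
    out = pd.DataFrame({"id": df["id"]})
    for locus in ("vgll3", "six6"):
        out[locus] = [
            float(encode_additive_genotype(v)) if v.strip() else np.nan
            for v in df[locus]
        ]
    out["sex"] = df["sex"].str.strip().str.lower().replace("", np.nan)
    return out
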