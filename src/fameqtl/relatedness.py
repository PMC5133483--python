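"""Pedigree kinship coefficients and the family block structure.

The kinship coefficient phi(i, j) is the probability that an allele drawn at
random from i and one drawn from j are identical by descent.  For a
non-inbred pedigree the recursion is

    phi(i, i) = 0.5 * (1 + phi(father_i, mother_i))
    phi(i, j) = 0.5 * (phi(father_i, j) + phi(mother_i, j))   for j processed
                                                              before i

with founders unrelated and phi(founder, founder) = 0.5.  Families are
mutually unrelated, so the matrix is block diagonal when samples are ordered
family-major; the mixed model exploits that by eigendecomposing one family
block at a time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import Pedigree, get_logger


@dataclass
class KinshipMatrix:
    """Symmetric kinship matrix with family block ranges.

    ``family_blocks`` holds (start, stop) index ranges into ``sample_ids``;
    entries between different blocks are exactly zero.
    """

    sample_ids: list[str]
    phi: np.ndarray
    family_blocks: list[tuple[int, int]]
    family_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.sample_ids)
        if self.phi.shape != (n, n):
            raise ValueError("phi shape does not match sample count")
        if not np.allclose(self.phi, self.phi.T, atol=1e-12):
            raise ValueError("phi is not symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def additive_relationship(self) -> np.ndarray:
        """K = 2*phi, the expected additive relationship matrix (diag 1 for
        non-inbred individuals); the covariance structure used by the model."""
        return 2.0 * self.phi

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.phi, index=self.sample_ids,
                     columns=self.sample_ids).to_csv(path, sep="\t")


def kinship_from_pedigree(pedigree: Pedigree,
                          extra_singletons: Sequence[str] = (),
                          ) -> KinshipMatrix:
    """Kinship matrix from a pedigree by the standard recursive rule.

    Samples are ordered family-major, parents before offspring, so the
    result is block diagonal with one block per family.  Ids in
    ``extra_singletons`` (genotyped individuals absent from the pedigree)
    are appended as singleton founder families with phi diagonal 0.5.
    """
    ped = pedigree.sorted_parents_first()
    t = ped.table
    ids: list[str] = []
    fam_of: list[str] = []
    blocks: list[tuple[int, int]] = []
    phi_blocks: list[np.ndarray] = []

    for fam, members in ped.families().items():
        m = len(members)
        idx = {iid: k for k, iid in enumerate(members)}
        sub = t[t["family"] == fam].set_index("individual")
        p = np.zeros((m, m))
        for k, iid in enumerate(members):
            f, mo = sub.loc[iid, "father"], sub.loc[iid, "mother"]
            if f is None:
                p[k, k] = 0.5
                # founders unrelated to everyone already placed
            else:
                fi, mi = idx[f], idx[mo]
                p[k, k] = 0.5 * (1.0 + p[fi, mi])
                for j in range(k):
                    p[k, j] = p[j, k] = 0.5 * (p[fi, j] + p[mi, j])
        blocks.append((len(ids), len(ids) + m))
        ids.extend(members)
        fam_of.extend([fam] * m)
        phi_blocks.append(p)

    for s in extra_singletons:
        blocks.append((len(ids), len(ids) + 1))
        ids.append(s)
        fam_of.append(f"singleton_{s}")
        phi_blocks.append(np.array([[0.5]]))
    if extra_singletons:
        get_logger().info("kinship: %d genotyped individuals outside the "
                          "pedigree treated as singleton founders",
                          len(extra_singletons))

    n = len(ids)
    phi = np.zeros((n, n))
    for (a, b), blk in zip(blocks, phi_blocks):
        phi[a:b, a:b] = blk
    return KinshipMatrix(ids, phi, blocks, fam_of)


def block_view(kinship: KinshipMatrix, sample_subset: Sequence[str],
               ) -> KinshipMatrix:
    """Restrict the kinship matrix to a sample subset and recompute blocks.

    The subset is re-sorted family-major (preserving relative order within a
    family) so the result stays block diagonal.
    """
    pos = {s: k for k, s in enumerate(kinship.sample_ids)}
    unknown = [s for s in sample_subset if s not in pos]
    if unknown:
        raise KeyError(f"samples not in kinship matrix: {unknown}")
    fam = kinship.family_ids or ["_" for _ in kinship.sample_ids]
    # group subset members by family, keeping first-seen family order
    by_fam: dict[str, list[str]] = {}
    for s in sample_subset:
        by_fam.setdefault(fam[pos[s]], []).append(s)
    ordered: list[str] = []
    blocks: list[tuple[int, int]] = []
    fam_of: list[str] = []
    for f, members in by_fam.items():
        blocks.append((len(ordered), len(ordered) + len(members)))
        ordered.extend(members)
        fam_of.extend([f] * len(members))
    rows = [pos[s] for s in ordered]
    sub = kinship.phi[np.ix_(rows, rows)]
    return KinshipMatrix(ordered, sub, blocks, fam_of)


# ---------------------------------------------------------------------------
# Gene-dropping Monte-Carlo oracle
# ---------------------------------------------------------------------------

def gene_drop_kinship(pedigree: Pedigree, n_loci: int,
                      rng: np.random.Generator) -> KinshipMatrix:
    """Estimate kinship by Monte-Carlo gene dropping over ``n_loci`` replicate
    unlinked loci.

    Each founder receives two globally unique allele labels; offspring draw
    one allele from each parent uniformly per locus.  phi(i, j) is estimated
    as the average over loci of the probability that a random allele from i
    matches (is identical by descent to) a random allele from j.
    """
    ped = pedigree.sorted_parents_first()
    t = ped.table
    ids = t["individual"].tolist()
    idx = {iid: k for k, iid in enumerate(ids)}
    n = len(ids)
    alleles = np.empty((n, 2, n_loci), dtype=np.int32)
    label = 0
    for k, (_, row) in enumerate(t.iterrows()):
        f, m = row["father"], row["mother"]
        if f is None:
            alleles[k, 0] = label
            alleles[k, 1] = label + 1
            label += 2
        else:
            pick_f = rng.integers(0, 2, n_loci)
            pick_m = rng.integers(0, 2, n_loci)
            alleles[k, 0] = alleles[idx[f], pick_f, np.arange(n_loci)]
            alleles[k, 1] = alleles[idx[m], pick_m, np.arange(n_loci)]

    phi = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            match = 0.0
            for a in range(2):
                for b in range(2):
                    if i == j and a == b:
                        match += float(n_loci)  # an allele is IBD with itself
                    else:
                        match += float(np.count_nonzero(
                            alleles[i, a] == alleles[j, b]))
            phi[i, j] = phi[j, i] = match / (4.0 * n_loci)

    fams = t["family"].tolist()
    blocks: list[tuple[int, int]] = []
    start = 0
    for k in range(1, n + 1):
        if k == n or fams[k] != fams[k - 1]:
            blocks.append((start, k))
            start = k
    return KinshipMatrix(ids, phi, blocks, fams)
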