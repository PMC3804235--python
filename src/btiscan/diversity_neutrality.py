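"""Sequence diversity summaries and neutrality statistics for candidate-gene
haplotype alignments.

The statistics contrast three estimators of the scaled mutation rate θ = 4Neμ:
mean pairwise differences K (π per site), Watterson's θ_W = S / a_n (from
segregating sites), and the singleton count η_s (from the tips of the
genealogy).  Under the standard neutral model their expectations coincide, so
standardized differences — Tajima's D and Fu & Li's D*/F* (the outgroup-free,
"starred" variants) — are centred near zero; an excess of intermediate-
frequency variants drives them positive (consistent with positive or balancing
selection), an excess of rare variants drives them negative (expansion,
purifying selection, or a recent sweep).

Sites containing ``N`` or an alignment gap are removed list-wise (every
haplotype loses that column) before any statistic is computed, mirroring the
behaviour of classic sequence-polymorphism software; per-site quantities are
scaled by the number of retained columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "HaplotypeAlignment",
    "DiversityStats",
    "NeutralityResult",
    "diversity_stats",
    "tajimas_d",
    "fu_li_d_star",
    "fu_li_f_star",
    "tajimas_d_from_summaries",
    "fu_li_d_star_from_summaries",
    "fu_li_f_star_from_summaries",
    "site_summaries_from_counts",
]

_VALID_BASES = frozenset(b"ACGT")
_MISSING = frozenset(b"N-")
_ALPHABET = frozenset(b"ACGTN-")


@dataclass(frozen=True)
class HaplotypeAlignment:
    """Aligned, phased haplotype sequences for one strain at one locus."""

    names: tuple
    sequences: tuple
    label: str = ""

    def __post_init__(self):
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences must have equal length")
        if not self.sequences:
            raise ValueError("alignment is empty")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(
                f"ragged alignment: sequence lengths {sorted(lengths)} differ"
            )
        for name, seq in zip(self.names, self.sequences):
            bad = set(seq.upper().encode()) - _ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains invalid symbols "
                    f"{sorted(chr(b) for b in bad)}; allowed: A,C,G,T,N,-"
                )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def to_matrix(self) -> np.ndarray:
        """n × L byte matrix of upper-case symbols."""
        return np.frombuffer(
            "".join(s.upper() for s in self.sequences).encode(), dtype="S1"
        ).reshape(self.n, self.length)

    def valid_columns(self) -> np.ndarray:
        """Boolean mask of columns free of N and gaps in every haplotype."""
        mat = self.to_matrix()
        mask = np.ones(self.length, dtype=bool)
        for sym in (b"N", b"-"):
            mask &= ~(mat == sym).any(axis=0)
        return mask


@dataclass
class DiversityStats:
    """Per-locus polymorphism summaries.

    S counts polymorphic columns once; eta counts one mutation per derived
    state (a tri-allelic column contributes 2), so S ≤ eta always.  pi is
    per valid site, K and theta_w are per locus.
    """

    n: int
    L_valid: int
    S: int
    eta: int
    eta_s: int
    pi: float
    Hd: float
    theta_w: float
    K_within: float
    K_between: Optional[float] = None


@dataclass
class NeutralityResult:
    statistic: str
    value: float
    analytic_band: str = "n.s."
    corrected_p: Optional[float] = None


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def _column_allele_counts(col: np.ndarray):
    vals, counts = np.unique(col, return_counts=True)
    return counts


def _singletons_in_column(counts: np.ndarray) -> int:
    # A singleton mutation is one whose variant is carried by exactly one
    # haplotype.  With k alleles a column holds k-1 mutations, so when every
    # allele is unique one of them is the "ancestral" background.
    k = len(counts)
    c1 = int(np.sum(counts == 1))
    if c1 == k:
        return k - 1
    return c1


def diversity_stats(
    aln: HaplotypeAlignment, other: Optional[HaplotypeAlignment] = None
) -> DiversityStats:
    """Compute S, η, η_s, π, Hd, θ_W and K for one alignment.

    When ``other`` is given, ``K_between`` is the mean number of pairwise
    differences over all cross-strain haplotype pairs, computed on columns
    valid in both alignments (the two loci must have equal length).
    """
    if aln.n < 2:
        raise ValueError("at least 2 haplotypes required")
    mask = aln.valid_columns()
    mat = aln.to_matrix()[:, mask]
    n, L_valid = aln.n, int(mask.sum())

    S = 0
    eta = 0
    eta_s = 0
    sum_pair_diff = 0.0
    n_pairs = n * (n - 1) / 2.0
    for j in range(mat.shape[1]):
        counts = _column_allele_counts(mat[:, j])
        k = len(counts)
        if k > 1:
            S += 1
            eta += k - 1
            eta_s += _singletons_in_column(counts)
            same = float(np.sum(counts * (counts - 1) / 2.0))
            sum_pair_diff += n_pairs - same

    K_within = sum_pair_diff / n_pairs
    pi = K_within / L_valid if L_valid > 0 else 0.0

    # haplotype diversity on the retained columns
    haplos = [row.tobytes() for row in mat]
    _, hcounts = np.unique(haplos, return_counts=True)
    freqs = hcounts / n
    Hd = (n / (n - 1)) * (1.0 - float(np.sum(freqs**2)))

    theta_w = S / _harmonic(n)

    K_between = None
    if other is not None:
        if other.length != aln.length:
            raise ValueError("alignments must have equal length for K_between")
        joint_mask = mask & other.valid_columns()
        a = aln.to_matrix()[:, joint_mask]
        b = other.to_matrix()[:, joint_mask]
        total = 0
        for i in range(a.shape[0]):
            total += int((a[i][None, :] != b).sum())
        K_between = total / (a.shape[0] * b.shape[0])

    return DiversityStats(
        n=n, L_valid=L_valid, S=S, eta=eta, eta_s=eta_s, pi=pi, Hd=Hd,
        theta_w=theta_w, K_within=K_within, K_between=K_between,
    )


# ---------------------------------------------------------------------------
# Neutrality statistics from summaries (usable on simulated site counts
# without materializing sequences).
# ---------------------------------------------------------------------------

def site_summaries_from_counts(derived_counts: Sequence[int], n: int):
    """(S, eta, eta_s, K) from per-site derived-allele counts of biallelic
    (infinite-sites) data with sample size n.

    Counts of 0 or n are monomorphic and ignored.  A singleton is a variant
    carried by exactly one haplotype: derived count 1 or n-1 (no outgroup).
    """
    c = np.asarray(derived_counts, dtype=float)
    c = c[(c > 0) & (c < n)]
    S = int(c.size)
    eta = S
    eta_s = int(np.sum((c == 1) | (c == n - 1)))
    K = float(np.sum(2.0 * c * (n - c)) / (n * (n - 1)))
    return S, eta, eta_s, K


def _tajima_constants(n: int):
    a1 = _harmonic(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d_from_summaries(n: int, S: int, K: float) -> float:
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if S < 1:
        raise ValueError("Tajima's D undefined when S = 0")
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    return (K - S / a1) / np.sqrt(var)


def _fu_li_constants(n: int):
    """Variance constants for the starred (no-outgroup) Fu & Li tests.

    Uses the corrected constant set adopted by reference implementations of
    the 1993 statistics: c_n and d_n below, with u/v split so that
    Var = u·η + v·η².
    """
    nf = float(n)
    an = _harmonic(n)
    bn = float(np.sum(1.0 / np.arange(1, n) ** 2))
    an1 = an + 1.0 / nf  # a_{n+1}

    cn = 2.0 * (nf * an - 2.0 * (nf - 1)) / ((nf - 1) * (nf - 2))
    dn = (
        cn
        + (nf - 2) / (nf - 1) ** 2
        + (2.0 / (nf - 1)) * (1.5 - (2.0 * an1 - 3.0) / (nf - 2) - 1.0 / nf)
    )

    v_d = (
        (nf / (nf - 1)) ** 2 * bn
        + an**2 * dn
        - 2.0 * nf * an * (an + 1.0) / (nf - 1) ** 2
    ) / (an**2 + bn)
    u_d = (nf / (nf - 1)) * (an - nf / (nf - 1)) - v_d

    v_f = (
        dn
        + 2.0 * (nf**2 + nf + 3.0) / (9.0 * nf * (nf - 1))
        - (2.0 / (nf - 1)) * (4.0 * bn - 6.0 + 8.0 / nf)
    ) / (an**2 + bn)
    u_f = (
        nf / (nf - 1)
        + (nf + 1) / (3.0 * (nf - 1))
        - 4.0 / (nf * (nf - 1))
        + 2.0 * (nf + 1) / (nf - 1) ** 2 * (an1 - 2.0 * nf / (nf + 1))
    ) / an - v_f

    return an, u_d, v_d, u_f, v_f


def fu_li_d_star_from_summaries(n: int, eta: int, eta_s: int) -> float:
    if n < 4:
        raise ValueError("Fu & Li's D* requires n >= 4")
    if eta < 1:
        raise ValueError("Fu & Li's D* undefined when there is no polymorphism")
    an, u_d, v_d, _, _ = _fu_li_constants(n)
    num = (n / (n - 1.0)) * eta - an * eta_s
    return num / np.sqrt(u_d * eta + v_d * eta**2)


def fu_li_f_star_from_summaries(n: int, K: float, eta: int, eta_s: int) -> float:
    if n < 4:
        raise ValueError("Fu & Li's F* requires n >= 4")
    if eta < 1:
        raise ValueError("Fu & Li's F* undefined when there is no polymorphism")
    _, _, _, u_f, v_f = _fu_li_constants(n)
    num = K - ((n - 1.0) / n) * eta_s
    return num / np.sqrt(u_f * eta + v_f * eta**2)


def tajimas_d(aln: HaplotypeAlignment) -> float:
    """Tajima's D: standardized K − θ_W (per locus)."""
    st = diversity_stats(aln)
    return tajimas_d_from_summaries(st.n, st.S, st.K_within)


def fu_li_d_star(aln: HaplotypeAlignment) -> float:
    """Fu & Li's D*: standardized contrast of total vs singleton mutations."""
    st = diversity_stats(aln)
    return fu_li_d_star_from_summaries(st.n, st.eta, st.eta_s)


def fu_li_f_star(aln: HaplotypeAlignment) -> float:
    """Fu & Li's F*: standardized contrast of pairwise diversity vs singletons."""
    st = diversity_stats(aln)
    return fu_li_f_star_from_summaries(st.n, st.K_within, st.eta, st.eta_s)
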