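"""Pairwise gene-interaction profiles and their two-sample scores.

A gene pair (g_i, g_j) is summarised per sample by one of four scalar
*interaction profiles* of the two expression values e_i(k), e_j(k):

=============  ====================  ==========================================
profile        definition            biological reading
=============  ====================  ==========================================
cooperation    e_i(k) + e_j(k)       joint activity of a functional module
competition    e_i(k) - e_j(k)       regulatory balance between antagonists
redundancy     max(e_i(k), e_j(k))   either gene suffices for the function
dependency     min(e_i(k), e_j(k))   both genes are required for the function
=============  ====================  ==========================================

A pair is *dysregulated* when its profile differs between the case and
control sample classes; the per-pair score is the classic two-sample
t-statistic of the profile values (pooled variance by default).

Useful identities, all consequences of max + min = sum:

* cooperation = redundancy + dependency (elementwise),
* redundancy >= dependency, with equality iff e_i = e_j,
* competition is antisymmetric in the gene order, the other three symmetric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ProfileKind",
    "PairScore",
    "compute_profile",
    "profile_matrix",
    "pair_score",
    "pathway_pair_scores",
    "two_sample_t",
]


class ProfileKind(str, Enum):
    """The closed set of four pairwise interaction profiles."""

    COOPERATION = "cooperation"
    COMPETITION = "competition"
    REDUNDANCY = "redundancy"
    DEPENDENCY = "dependency"

    @classmethod
    def coerce(cls, value: "ProfileKind | str") -> "ProfileKind":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValidationError(
                f"unknown profile kind {value!r}; expected one of "
                f"{[k.value for k in cls]}"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class PairScore:
    """Two-sample score of one gene pair under one profile.

    ``z`` is the equal-variance two-sample t-statistic of the profile
    between case and control samples (positive = higher in cases).
    ``constant`` flags a profile with zero pooled variance, which carries
    no signal and is scored 0 so that pathway statistics keep a fixed
    number of entries across permutations.
    """

    gene_i: str
    gene_j: str
    kind: ProfileKind
    z: float
    constant: bool = False


def compute_profile(e_i: np.ndarray, e_j: np.ndarray, kind: ProfileKind | str) -> np.ndarray:
    """Per-sample interaction profile of two expression vectors."""
    kind = ProfileKind.coerce(kind)
    e_i = np.asarray(e_i, dtype=float)
    e_j = np.asarray(e_j, dtype=float)
    if e_i.shape != e_j.shape or e_i.ndim != 1:
        raise ValidationError(
            f"expression vectors must be 1-d and of equal length, got "
            f"shapes {e_i.shape} and {e_j.shape}"
        )
    if e_i.size < 1:
        raise ValidationError("expression vectors must have length >= 1")
    if kind is ProfileKind.COOPERATION:
        return e_i + e_j
    if kind is ProfileKind.COMPETITION:
        return e_i - e_j
    if kind is ProfileKind.REDUNDANCY:
        return np.maximum(e_i, e_j)
    return np.minimum(e_i, e_j)


def profile_matrix(X: np.ndarray, kind: ProfileKind | str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Profiles for every unordered pair of rows of ``X``.

    Parameters
    ----------
    X : (k, m) array
        Expression of the k pathway genes across m samples, rows ordered
        lexicographically by gene symbol (the convention under which the
        competition profile is computed as row_i - row_j with i < j).

    Returns
    -------
    (V, ii, jj)
        ``V`` is the (k*(k-1)/2, m) profile matrix; ``ii``/``jj`` index
        the gene rows of each pair, with ``ii < jj``.
    """
    kind = ProfileKind.coerce(kind)
    X = np.asarray(X, dtype=float)
    k = X.shape[0]
    if k < 2:
        raise ValidationError("need at least 2 genes to form pairs")
    ii, jj = np.triu_indices(k, 1)
    A, B = X[ii], X[jj]
    if kind is ProfileKind.COOPERATION:
        V = A + B
    elif kind is ProfileKind.COMPETITION:
        V = A - B
    elif kind is ProfileKind.REDUNDANCY:
        V = np.maximum(A, B)
    else:
        V = np.minimum(A, B)
    return V, ii, jj


def two_sample_t(
    V: np.ndarray,
    case_mask: np.ndarray,
    equal_var: bool = True,
) -> np.ndarray:
    """Row-wise two-sample t-statistics, case minus control.

    ``V`` may be 1-d (one variable) or 2-d (variables x samples). Rows with
    zero within-group variance in both groups score exactly 0. The pooled
    (equal-variance) form is the default; ``equal_var=False`` gives Welch.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    y = np.asarray(case_mask, dtype=bool)
    if V.shape[1] != y.size:
        raise ValidationError(
            f"profile has {V.shape[1]} samples but mask has {y.size}"
        )
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    if n1 < 2 or n0 < 2:
        raise ValidationError("need >= 2 samples per class for a t-statistic")
    m1 = V[:, y].mean(axis=1)
    m0 = V[:, ~y].mean(axis=1)
    ss1 = ((V[:, y] - m1[:, None]) ** 2).sum(axis=1)
    ss0 = ((V[:, ~y] - m0[:, None]) ** 2).sum(axis=1)
    if equal_var:
        sp2 = (ss1 + ss0) / (n1 + n0 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    else:
        se = np.sqrt(ss1 / (n1 * (n1 - 1)) + ss0 / (n0 * (n0 - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / se
    t[~np.isfinite(t)] = 0.0
    return t


def pair_score(
    profile: np.ndarray,
    case_mask: np.ndarray,
    *,
    gene_i: str = "",
    gene_j: str = "",
    kind: ProfileKind | str = ProfileKind.COOPERATION,
    equal_var: bool = True,
) -> PairScore:
    """Score one pair's profile; constant profiles get z = 0 and a flag."""
    kind = ProfileKind.coerce(kind)
    t = float(two_sample_t(profile, case_mask, equal_var=equal_var)[0])
    profile = np.asarray(profile, dtype=float)
    y = np.asarray(case_mask, dtype=bool)
    constant = bool(
        np.ptp(profile[y]) == 0.0 and np.ptp(profile[~y]) == 0.0
    )
    return PairScore(gene_i=gene_i, gene_j=gene_j, kind=kind, z=t, constant=constant)


def pathway_pair_scores(
    ds,
    pathway_genes,
    kind: ProfileKind | str,
    *,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Z-scores of every unordered gene pair of a pathway.

    Genes absent from the dataset are dropped; the surviving genes are
    sorted lexicographically and each of the C(k, 2) pairs is scored once
    (for competition this fixes the sign convention; the pathway-level
    maxmean statistic is invariant to it).

    Returns a DataFrame with columns gene_i, gene_j, kind, z, constant.
    Raises :class:`ValidationError` if fewer than 2 genes match.
    """
    kind = ProfileKind.coerce(kind)
    genes = sorted(set(g.upper() for g in pathway_genes) & set(ds.genes))
    if len(genes) < 2:
        raise ValidationError(
            f"pathway has {len(genes)} gene(s) in the dataset; need >= 2"
        )
    idx = [ds.gene_index[g] for g in genes]
    X = ds.values[idx]
    V, ii, jj = profile_matrix(X, kind)
    z = two_sample_t(V, ds.case_mask, equal_var=equal_var)
    y = ds.case_mask
    const = (np.ptp(V[:, y], axis=1) == 0.0) & (np.ptp(V[:, ~y], axis=1) == 0.0)
    return pd.DataFrame(
        {
            "gene_i": [genes[a] for a in ii],
            "gene_j": [genes[b] for b in jj],
            "kind": kind.value,
            "z": z,
            "constant": const,
        }
    )


def all_pairs(genes) -> list[tuple[str, str]]:
    """Lexicographically ordered unordered pairs of a gene collection."""
    return list(itertools.combinations(sorted(genes), 2))
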