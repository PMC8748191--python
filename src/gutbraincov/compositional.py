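"""Compositional containers and the log-contrast balance statistic.

Relative-abundance data carry information only in ratios: multiplying a
sample's row by any positive constant (sequencing depth, closure to
proportions) must not change an analysis.  The *balance* between two
disjoint groups of taxa A and B,

    B_i = c * log( gmean_{a in A}(x_ia) / gmean_{b in B}(x_ib) ),

is the canonical scale-invariant contrast: positive values mean the A
taxa are jointly more abundant than the B taxa.  The normalization
``c = sqrt(|A||B| / (|A|+|B|))`` turns the contrast into an isometric
log-ratio coordinate; by default ``c = 1`` (the plain log-ratio of
geometric means, the scale on which phylum-level signatures are usually
reported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "BalanceSignature",
    "filter_prevalence",
    "replace_zeros",
    "compute_balance",
]

_LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0, 2: 2.0, 10: 10.0}


class EmptyTableError(ValueError):
    """All taxa (or samples) were removed from a table."""


@dataclass
class AbundanceTable:
    """Samples x taxa nonnegative abundance matrix (counts or proportions).

    Parameters
    ----------
    sample_ids, taxon_ids : identifiers; taxon ids must be unique.
    values : array of shape ``(n_samples, n_taxa)``, nonnegative, each
        row summing to a positive total.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x taxa)")
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("taxon_ids must be unique")
        if np.any(self.values < 0):
            raise ValueError("abundances must be nonnegative")
        if np.any(self.values.sum(axis=1) <= 0):
            raise ValueError("every sample row must have a positive total")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def zero_fraction(self) -> pd.Series:
        """Per-taxon fraction of samples in which the taxon is absent."""
        return pd.Series((self.values == 0).mean(axis=0), index=self.taxon_ids)

    def taxon_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in ids if t not in lookup]
        if missing:
            raise KeyError(f"taxa not in table: {missing}")
        return np.array([lookup[t] for t in ids], dtype=int)

    def subset_taxa(self, ids: Sequence[str]) -> "AbundanceTable":
        idx = self.taxon_index(ids)
        return AbundanceTable(list(self.sample_ids), list(ids), self.values[:, idx])

    def close(self) -> "AbundanceTable":
        """Return the table with rows rescaled to proportions summing to 1."""
        vals = self.values / self.values.sum(axis=1, keepdims=True)
        return AbundanceTable(list(self.sample_ids), list(self.taxon_ids), vals)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceTable":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(float))

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "AbundanceTable":
        return cls.from_dataframe(pd.read_csv(path, sep="\t", index_col=0))


@dataclass(frozen=True)
class BalanceSignature:
    """Disjoint numerator (A) / denominator (B) taxon sets defining a balance."""

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    log_base: str | int = "e"
    use_ilr_coefficient: bool = False
    score: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "numerator", tuple(self.numerator))
        object.__setattr__(self, "denominator", tuple(self.denominator))
        if not self.numerator or not self.denominator:
            raise ValueError("numerator and denominator must be nonempty")
        if set(self.numerator) & set(self.denominator):
            raise ValueError("numerator and denominator must be disjoint")
        if self.log_base not in _LOG_BASES:
            raise ValueError(f"log_base must be one of {{'e', 2, 10}}, got {self.log_base!r}")

    @property
    def size(self) -> int:
        return len(self.numerator) + len(self.denominator)

    @property
    def coefficient(self) -> float:
        if not self.use_ilr_coefficient:
            return 1.0
        a, b = len(self.numerator), len(self.denominator)
        return math.sqrt(a * b / (a + b))

    def swapped(self) -> "BalanceSignature":
        return replace(self, numerator=self.denominator, denominator=self.numerator)

    def key(self) -> str:
        """Canonical string identifier (order within sides ignored)."""
        return "+".join(sorted(self.numerator)) + " / " + "+".join(sorted(self.denominator))

    def as_dict(self) -> dict:
        return {
            "numerator": sorted(self.numerator),
            "denominator": sorted(self.denominator),
            "log_base": str(self.log_base),
            "coefficient": self.coefficient,
            "score": self.score,
        }


def filter_prevalence(table: AbundanceTable, max_zero_fraction: float = 0.20) -> AbundanceTable:
    """Drop taxa absent in more than ``max_zero_fraction`` of the samples.

    Retains exactly the taxa whose zero fraction is <= the threshold; the
    sample set is unchanged.  Raises :class:`EmptyTableError` if nothing
    survives.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must be in [0, 1]")
    zf = table.zero_fraction().to_numpy()
    keep = [t for t, z in zip(table.taxon_ids, zf) if z <= max_zero_fraction]
    if not keep:
        raise EmptyTableError(
            f"no taxon has a zero fraction <= {max_zero_fraction}; table would be empty"
        )
    return table.subset_taxa(keep)


def replace_zeros(
    table: AbundanceTable,
    pseudocount: float = 0.5,
    kind: str = "auto",
    depth: float = 5000.0,
) -> AbundanceTable:
    """Replace exact zeros by a small positive value; nonzero cells untouched.

    For count tables the replacement is ``pseudocount`` itself; for
    proportion tables it is ``pseudocount / depth`` (the pseudocount
    expressed on the proportion scale for an assumed read depth).  The
    operation is idempotent.

    Parameters
    ----------
    kind : {'auto', 'counts', 'proportions'}
        'auto' treats the table as proportions when every row sums to 1.
    depth : assumed read depth used to scale the pseudocount for
        proportion tables.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if kind not in ("auto", "counts", "proportions"):
        raise ValueError(f"unknown kind {kind!r}")
    if kind == "auto":
        sums = table.values.sum(axis=1)
        kind = "proportions" if np.allclose(sums, 1.0, atol=1e-6) else "counts"
    fill = pseudocount if kind == "counts" else pseudocount / float(depth)
    vals = table.values.copy()
    vals[vals == 0] = fill
    return AbundanceTable(list(table.sample_ids), list(table.taxon_ids), vals)


def compute_balance(table: AbundanceTable, sig: BalanceSignature) -> np.ndarray:
    """Per-sample balance ``c * log(gmean(A) / gmean(B))``.

    The table must be strictly positive on A union B (apply
    :func:`replace_zeros` first).  The statistic is invariant to
    per-sample rescaling, so counts and proportions give identical
    values.
    """
    ia = table.taxon_index(sig.numerator)
    ib = table.taxon_index(sig.denominator)
    sub = table.values[:, np.concatenate([ia, ib])]
    if np.any(sub <= 0):
        s, t = np.argwhere(sub <= 0)[0]
        names = list(sig.numerator) + list(sig.denominator)
        raise ValueError(
            f"non-positive abundance for taxon {names[t]!r} in sample "
            f"{table.sample_ids[s]!r}; apply replace_zeros first"
        )
    log = np.log(sub)
    la, lb = log[:, : len(ia)], log[:, len(ia):]
    bal = la.mean(axis=1) - lb.mean(axis=1)
    bal *= sig.coefficient / math.log(_LOG_BASES[sig.log_base])
    return bal
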