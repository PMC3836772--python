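"""Empirical hydrophobicity scales from solvent-accessibility statistics.

A residue's average burial across many structures reflects its aversion to
water, so per-amino-acid exposure statistics define empirical
hydrophobicity scales:

* mean-RSA scale: 1 - mean relative solvent accessibility (larger = more
  hydrophobic);
* fraction 100% buried: how often the amino acid has zero accessible
  area;
* fraction 95% buried: how often its RSA falls at or below a small
  threshold (default 0.05).

These can be correlated (Pearson, over the 20 amino acids, absolute value
reported) against packaged experimentally measured scales.  Note that
|r| is invariant under affine transforms of either scale, so the sign and
offset conventions above do not affect any correlation.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .normtables import AMINO_ACIDS, NormalizationScale
from .survey import unflagged

__all__ = [
    "HydrophobicityScale",
    "mean_rsa_scale",
    "fraction_buried",
    "correlate",
    "experimental_scales",
    "correlation_table",
]

DERIVATIONS = ("mean-rsa", "frac-100-buried", "frac-95-buried", "experimental")


@dataclass(frozen=True)
class HydrophobicityScale:
    """Amino acid -> hydrophobicity score, tagged by derivation."""

    name: str
    derivation: str
    scores: dict

    def __post_init__(self):
        if self.derivation not in DERIVATIONS:
            raise ValueError(f"unknown derivation {self.derivation!r}")
        if set(self.scores) != set(AMINO_ACIDS):
            raise ValueError("scale must cover the 20 canonical amino acids")
        if not all(np.isfinite(list(self.scores.values()))):
            raise ValueError("scores must be finite")

    def __getitem__(self, aa: str) -> float:
        return self.scores[aa]

    def as_array(self) -> np.ndarray:
        return np.array([self.scores[aa] for aa in AMINO_ACIDS])


def _check_coverage(obs: pd.DataFrame) -> pd.DataFrame:
    sub = unflagged(obs)
    missing = set(AMINO_ACIDS) - set(sub.aa.unique())
    if missing:
        raise ValueError(
            f"no unflagged observations for: {''.join(sorted(missing))}")
    return sub


def mean_rsa_scale(obs: pd.DataFrame, scale: NormalizationScale,
                   name: str = "mean-rsa") -> HydrophobicityScale:
    """Hydrophobicity as 1 - mean RSA under the given normalization."""
    sub = _check_coverage(obs)
    scores = {}
    for aa, group in sub.groupby("aa"):
        scores[aa] = 1.0 - float(np.mean(group.asa / scale[aa]))
    return HydrophobicityScale(name, "mean-rsa", scores)


def fraction_buried(obs: pd.DataFrame, mode: str = "rsa-threshold",
                    threshold: float = 0.05,
                    scale: NormalizationScale | None = None,
                    name: str | None = None) -> HydrophobicityScale:
    """Fraction of occurrences in a buried state.

    ``mode="absolute-zero"`` counts residues with exactly zero ASA (the
    fully buried state); ``mode="rsa-threshold"`` counts RSA <=
    ``threshold`` under ``scale`` (required; the theoretical ALLOWED
    scale in typical use).
    """
    sub = _check_coverage(obs)
    scores = {}
    if mode == "absolute-zero":
        derivation = "frac-100-buried"
        for aa, group in sub.groupby("aa"):
            scores[aa] = float(np.mean(group.asa == 0.0))
    elif mode == "rsa-threshold":
        derivation = "frac-95-buried"
        if scale is None:
            raise ValueError("rsa-threshold mode needs a normalization scale")
        for aa, group in sub.groupby("aa"):
            scores[aa] = float(np.mean(group.asa / scale[aa] <= threshold))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return HydrophobicityScale(name or derivation, derivation, scores)


def correlate(a: HydrophobicityScale, b: HydrophobicityScale) -> tuple:
    """(|r|, p) Pearson correlation over the 20 amino acids."""
    x, y = a.as_array(), b.as_array()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a hydrophobicity scale")
    r, p = stats.pearsonr(x, y)
    return abs(float(r)), float(p)


@functools.lru_cache(maxsize=1)
def experimental_scales() -> dict:
    """Packaged experimentally measured hydrophobicity scales."""
    with resources.files("maxasa.data").joinpath(
            "experimental_hydrophobicity.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", index_col="aa")
    return {col: HydrophobicityScale(col, "experimental", df[col].to_dict())
            for col in df.columns}


def correlation_table(empirical: dict, experimental: dict | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Correlation matrix: experimental scales (rows) x empirical (columns).

    Cells hold |r|; a ``*_significant`` companion column marks p < alpha
    (no multiple-testing correction).
    """
    experimental = experimental or experimental_scales()
    rows = []
    for exp_name, exp_scale in experimental.items():
        row: dict = {"experimental": exp_name}
        for emp_name, emp_scale in empirical.items():
            r, p = correlate(emp_scale, exp_scale)
            row[emp_name] = r
            row[f"{emp_name}_significant"] = bool(p < alpha)
        rows.append(row)
    return pd.DataFrame(rows).set_index("experimental")
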