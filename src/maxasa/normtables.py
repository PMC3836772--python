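"""Published and derived ASA normalization constants.

Ships the proposed theoretical and empirical maximum-ASA scales (ALLOWED
Ramachandran region) together with the two historic scales they supersede:
the extended-conformation values of Miller et al. (1987) and the
average-conformation values of Rose et al. (1985).  All constants are in
square Angstroms per amino acid.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "NormalizationScale",
    "PROVENANCES",
    "get_scale",
    "correction_vs",
    "load_table",
]

PROVENANCES = ("theoretical", "empirical", "miller1987", "rose1985")
AMINO_ACIDS = tuple("ARNDCEQGHILKMFPSTWYV")


@dataclass(frozen=True)
class NormalizationScale:
    """Amino acid -> maximum ASA (A^2), tagged by provenance and region."""

    provenance: str
    region: str
    values_by_aa: dict

    def __post_init__(self):
        if set(self.values_by_aa) != set(AMINO_ACIDS):
            raise ValueError("scale must cover the 20 canonical amino acids")
        if any(v <= 0 for v in self.values_by_aa.values()):
            raise ValueError("maximum ASA values must be positive")

    def __getitem__(self, aa: str) -> float:
        return self.values_by_aa[aa]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"aa": list(self.values_by_aa),
             "max_asa": list(self.values_by_aa.values()),
             "provenance": self.provenance, "region": self.region})


@functools.lru_cache(maxsize=1)
def load_table() -> pd.DataFrame:
    """The packaged normalization table (one row per amino acid)."""
    with resources.files("maxasa.data").joinpath(
            "normalization_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="aa")


def get_scale(provenance: str, region: str = "ALLOWED") -> NormalizationScale:
    """A packaged normalization scale.

    The theoretical and empirical scales are the ALLOWED-region maxima;
    other regions are not transcribed (they can be regenerated with the
    scan module).  The Miller and Rose scales carry no region tag.
    """
    if provenance not in PROVENANCES:
        raise ValueError(f"unknown provenance {provenance!r}")
    if provenance in ("theoretical", "empirical") and region != "ALLOWED":
        raise ValueError(
            f"only the ALLOWED region is shipped for {provenance!r}")
    table = load_table()
    region_tag = region if provenance in ("theoretical", "empirical") else ""
    return NormalizationScale(provenance, region_tag,
                              table[provenance].to_dict())


def correction_vs(scale_a: NormalizationScale,
                  scale_b: NormalizationScale) -> dict:
    """Percent correction of ``scale_a`` relative to ``scale_b``.

    100 * (a - b) / a per amino acid, rounded to the nearest integer
    percent (the denominator is the first scale).
    """
    if set(scale_a.values_by_aa) != set(scale_b.values_by_aa):
        raise ValueError("scales cover different amino acids")
    out = {}
    for aa, a in scale_a.values_by_aa.items():
        if a == 0:
            raise ZeroDivisionError(f"zero maximum ASA for {aa}")
        out[aa] = int(round(100.0 * (a - scale_b.values_by_aa[aa]) / a))
    return out
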