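"""Spectral-count interactome comparison between two baits.

Processes label-free affinity-purification mass-spectrometry results where
protein abundance is proxied by spectral counts (number of MS/MS spectra
matched to a protein). Proteins are filtered against matched IgG control
runs, then compared between the two baits with the spectral index

    SI = (avgA - avgB) / (avgA + avgB)

where avgA and avgB are the mean counts over each bait's runs: +1 means
exclusive to bait A, -1 exclusive to bait B, 0 equal recovery. With the
typical two replicates per bait no variance-based test is possible, so the
module deliberately reports point estimates and threshold-based classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

BAITS = ("A", "B", "IgG")


@dataclass
class SpectralCountTable:
    """Protein x run spectral counts with bait annotations.

    ``counts``: DataFrame, proteins as rows, run ids as columns.
    ``baits``: run id -> bait class ("A", "B" or "IgG").
    ``passes_confidence``: per-protein boolean; proteins failing upstream
    peptide/protein identification-confidence thresholds never reach the
    spectral index.
    """

    counts: pd.DataFrame
    baits: dict[str, str]
    passes_confidence: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
            raise DataError("spectral counts must be non-negative integers")
        unknown = set(self.baits.values()) - set(BAITS)
        if unknown:
            raise ConfigError(f"unknown bait classes: {sorted(unknown)}")
        missing = set(self.counts.columns) - set(self.baits)
        if missing:
            raise ConfigError(f"runs without bait annotation: {sorted(missing)}")
        if self.passes_confidence is None:
            self.passes_confidence = pd.Series(True, index=self.counts.index)
        else:
            self.passes_confidence = self.passes_confidence.reindex(
                self.counts.index, fill_value=False
            ).astype(bool)

    def runs_for(self, bait: str) -> list[str]:
        return [r for r in self.counts.columns if self.baits[r] == bait]

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, path) -> None:
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["protein", "run", "count"]
        long["bait"] = long["run"].map(self.baits)
        long["passes_confidence"] = long["protein"].map(self.passes_confidence)
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpectralCountTable":
        long = pd.read_csv(path, sep="\t")
        required = {"protein", "run", "bait", "count"}
        if not required <= set(long.columns):
            raise DataError(f"spectral TSV needs columns {sorted(required)}")
        counts = long.pivot_table(
            index="protein", columns="run", values="count", aggfunc="sum", fill_value=0
        )
        counts.columns.name = None
        baits = dict(long.drop_duplicates("run")[["run", "bait"]].values)
        flags = None
        if "passes_confidence" in long.columns:
            flags = long.drop_duplicates("protein").set_index("protein")[
                "passes_confidence"
            ].astype(bool)
        return cls(counts, baits, flags)


def _bait_means(table: SpectralCountTable) -> pd.DataFrame:
    out = {}
    for bait in BAITS:
        runs = table.runs_for(bait)
        out[bait] = table.counts[runs].mean(axis=1) if runs else pd.Series(
            np.nan, index=table.counts.index
        )
    return pd.DataFrame(out)


def filter_background(
    table: SpectralCountTable, fold_min: float = 2.0, count_min: float = 2.0
) -> pd.Series:
    """Flag proteins enriched over the IgG background.

    A protein is retained iff max(avgA, avgB) >= fold_min x mean IgG count
    and max(avgA, avgB) >= count_min. Returns a boolean Series; proteins
    failing the identification-confidence flags are never retained. Nothing
    is dropped from the table itself — removed proteins are labelled
    "filtered" downstream.
    """
    if not table.runs_for("IgG"):
        raise ConfigError("background filtering requires >= 1 IgG run")
    means = _bait_means(table)
    best_bait = means[["A", "B"]].max(axis=1)
    keep = (best_bait >= fold_min * means["IgG"]) & (best_bait >= count_min)
    return keep & table.passes_confidence


def spectral_index(
    table: SpectralCountTable, retained: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Per-protein spectral index between the two baits.

    Returns a DataFrame with avg_a, avg_b, si and defined (False when
    avgA + avgB = 0, in which case no numeric SI is emitted), restricted to
    confidence-passing proteins. ``retained`` (from
    :func:`filter_background`) marks which proteins survive background
    filtering; the rest keep their SI but are classed "filtered".
    """
    if not table.runs_for("A") or not table.runs_for("B"):
        raise ConfigError("spectral index needs >= 1 run for each bait")
    means = _bait_means(table)
    tested = table.passes_confidence
    means = means.loc[tested]
    total = means["A"] + means["B"]
    defined = total > 0
    si = pd.Series(np.nan, index=means.index)
    si[defined] = (means.loc[defined, "A"] - means.loc[defined, "B"]) / total[defined]
    out = pd.DataFrame(
        {"avg_a": means["A"], "avg_b": means["B"], "si": si, "defined": defined}
    )
    out.index.name = "protein"
    if retained is not None:
        out["retained"] = retained.reindex(out.index, fill_value=False)
    else:
        out["retained"] = True
    return out


def classify(results: pd.DataFrame, si_cut: float = 0.33) -> pd.Series:
    """Assign preference classes from the spectral index.

    si >= si_cut -> "A-preferential"; si <= -si_cut -> "B-preferential";
    in between -> "shared". Proteins not retained by background filtering or
    with undefined SI -> "filtered".
    """
    if not 0 < si_cut < 1:
        raise ConfigError("si_cut must be in (0, 1)")
    labels = pd.Series("shared", index=results.index, dtype=object)
    labels[results["si"] >= si_cut] = "A-preferential"
    labels[results["si"] <= -si_cut] = "B-preferential"
    labels[~results["defined"] | ~results["retained"]] = "filtered"
    return labels
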