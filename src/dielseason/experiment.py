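"""Root data container for a replicated photoperiod time-course experiment.

A :class:`TimeCourseExperiment` couples a genes x libraries count matrix with
the library design (photoperiod, zeitgeber time, replicate) and per-gene
spike-in flags.  Every downstream stage — normalization, differential
screening, daily-expression-integral statistics, clustering — consumes this
object or tables derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Default mapping of photoperiod label to hours of light per 24-h day.
PHOTOPERIOD_HOURS = {"SD": 8, "EQ": 12, "LD": 16}

#: Default sampling grid: every 4 h across one diel cycle, ZT0 = dawn.
DEFAULT_TIMEPOINTS = (0, 4, 8, 12, 16, 20)


@dataclass
class TimeCourseExperiment:
    """Counts plus design plus spike-in flags.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes (rows) x libraries (columns).
    design
        One row per library (index = library id) with columns
        ``photoperiod``, ``zt`` and ``replicate``.
    spikein
        Boolean Series indexed like ``counts`` rows; True marks spike-in
        control rows, which are excluded from normalization and testing.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    spikein: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.spikein is None:
            self.spikein = pd.Series(False, index=self.counts.index)
        self.validate()

    def validate(self) -> None:
        if self.counts.shape[1] < 2:
            raise ValueError("an experiment needs at least 2 libraries")
        if not self.counts.columns.equals(pd.Index(self.design.index)):
            if set(self.counts.columns) != set(self.design.index):
                raise ValueError("design rows must match count columns exactly")
            self.design = self.design.loc[self.counts.columns]
        if self.design.index.has_duplicates:
            raise ValueError("every library must appear in the design exactly once")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("counts must be finite and non-negative")
        missing = {"photoperiod", "zt", "replicate"} - set(self.design.columns)
        if missing:
            raise ValueError(f"design is missing columns: {sorted(missing)}")
        if not self.spikein.index.equals(self.counts.index):
            raise ValueError("spike-in flags must be indexed like the count rows")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def photoperiods(self) -> list[str]:
        return list(pd.unique(self.design["photoperiod"]))

    @property
    def timepoints(self) -> list[float]:
        return sorted(pd.unique(self.design["zt"]))

    def libraries_for(self, photoperiod: str, zt: float | None = None) -> list[str]:
        """Library ids of one photoperiod (optionally one time point)."""
        mask = self.design["photoperiod"] == photoperiod
        if zt is not None:
            mask &= self.design["zt"] == zt
        return list(self.design.index[mask])

    def without_spikeins(self) -> "TimeCourseExperiment":
        keep = ~self.spikein
        return TimeCourseExperiment(
            counts=self.counts.loc[keep],
            design=self.design.copy(),
            spikein=self.spikein.loc[keep],
        )

    # -- I/O -------------------------------------------------------------------

    def to_files(self, counts_path: str | Path, design_path: str | Path,
                 spikein_path: str | Path | None = None) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(counts_path, sep="\t")
        d = self.design.copy()
        d.index.name = "library_id"
        d.to_csv(design_path, sep="\t")
        if spikein_path is not None:
            ids = self.counts.index[self.spikein]
            Path(spikein_path).write_text("".join(f"{g}\n" for g in ids))

    @classmethod
    def from_files(cls, counts_path: str | Path, design_path: str | Path,
                   spikein_path: str | Path | None = None) -> "TimeCourseExperiment":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col=0)
        spike = pd.Series(False, index=counts.index)
        if spikein_path is not None and Path(spikein_path).exists():
            ids = [line.strip() for line in Path(spikein_path).read_text().splitlines()
                   if line.strip()]
            spike.loc[spike.index.intersection(ids)] = True
        return cls(counts=counts, design=design, spikein=spike)


def mean_by_timepoint(expression: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Average expression over replicates for every (photoperiod, ZT) group.

    Returns a genes x conditions frame whose columns are a MultiIndex
    (photoperiod, zt).  This replicate-mean table is the common input for
    DEI integration, pattern clustering, and phase fitting.
    """
    groups = design.groupby(["photoperiod", "zt"], sort=True).groups
    cols = {}
    for (pp, zt), libs in groups.items():
        cols[(pp, float(zt))] = expression[list(libs)].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["photoperiod", "zt"])
    return out
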