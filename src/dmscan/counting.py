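"""Variant x timepoint count tables for a single selection.

A selection is sampled at an input timepoint (t0) and one or more later
timepoints (rounds of panning, or hours of growth).  Counts per variant are
assembled into a matrix with per-timepoint read totals N_t; frequencies and
the filtered library size (the no-wild-type normalization denominator) are
derived from it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .refseq import WILD_TYPE_LABEL


@dataclass(frozen=True)
class TimepointSchedule:
    """Ordered timepoints for a selection; the first is the input (t0).

    Regression is performed on the normalized axis t / max(T), so schedules
    in rounds (0,1,...,5) and hours (0,24,...,120) are comparable.
    """

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) < 2:
            raise ValueError("a schedule needs at least two timepoints")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if max(self.times) <= 0:
            raise ValueError("max timepoint must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def normalized(self) -> np.ndarray:
        """t / max(T) for each timepoint."""
        return np.asarray(self.times, dtype=float) / max(self.times)


class VariantCountTable:
    """Nonnegative integer counts per variant per timepoint for one selection.

    Parameters
    ----------
    counts
        DataFrame indexed by variant label, one column per timepoint, in
        schedule order.
    schedule
        The selection's `TimepointSchedule`.
    read_totals
        Total accepted reads N_t per timepoint.  Defaults to the column
        sums (appropriate when every accepted read was assigned a variant).
        N_t may exceed the assigned column sum.
    wild_type
        Label of the wild-type row, if present.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        schedule: TimepointSchedule,
        read_totals: Optional[Sequence[float]] = None,
        wild_type: Optional[str] = WILD_TYPE_LABEL,
    ):
        if counts.shape[1] != len(schedule):
            raise ValueError(
                f"{counts.shape[1]} count columns but {len(schedule)} timepoints"
            )
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        arr = counts.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64)
        self.schedule = schedule
        if read_totals is None:
            self.read_totals = self.counts.sum(axis=0).astype(float).to_numpy()
        else:
            self.read_totals = np.asarray(read_totals, dtype=float)
            if len(self.read_totals) != len(schedule):
                raise ValueError("read_totals length must match schedule")
        if wild_type is not None and wild_type not in counts.index:
            wild_type = None
        self.wild_type = wild_type

    @property
    def variants(self) -> pd.Index:
        return self.counts.index

    @property
    def n_timepoints(self) -> int:
        return len(self.schedule)

    def frequencies(self) -> pd.DataFrame:
        """Per-timepoint variant frequencies f_{v,t} = c_{v,t} / N_t."""
        zero = np.flatnonzero(self.read_totals == 0)
        if zero.size:
            t = self.schedule.times[zero[0]]
            raise ValueError(f"read total N_t is zero at timepoint t={t}")
        return self.counts / self.read_totals

    def always_present(self) -> pd.Index:
        """Variants with a nonzero count at every timepoint."""
        return self.counts.index[(self.counts > 0).all(axis=1)]

    def filtered_library_size(self, t: Optional[int] = None):
        """Sum of counts over variants present at *all* timepoints.

        Used as the normalization denominator for libraries without a
        wild-type sequence.  ``t`` is the timepoint column index; when
        omitted, the full per-timepoint vector is returned.
        """
        present = self.always_present()
        if len(present) == 0:
            warnings.warn(
                "no variant is present at every timepoint; "
                "filtered library size is 0",
                stacklevel=2,
            )
        sizes = self.counts.loc[present].sum(axis=0)
        if t is None:
            return sizes
        return int(sizes.iloc[t])

    def input_present(self) -> pd.Index:
        """Variants eligible for scoring: nonzero count in the input."""
        return self.counts.index[self.counts.iloc[:, 0] > 0]

    # -- persistence ------------------------------------------------------

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Write counts as TSV plus a JSON sidecar with schedule and N_t."""
        path = Path(path)
        out = self.counts.copy()
        out.columns = [_time_label(t) for t in self.schedule.times]
        out.to_csv(path, sep="\t", index_label="variant")
        sidecar = {
            "times": list(self.schedule.times),
            "read_totals": [float(n) for n in self.read_totals],
            "wild_type": self.wild_type,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1) + "\n"
        )

    @classmethod
    def from_tsv(
        cls,
        path: Union[str, Path],
        times: Optional[Sequence[float]] = None,
        read_totals: Optional[Sequence[float]] = None,
        wild_type: Optional[str] = WILD_TYPE_LABEL,
    ) -> "VariantCountTable":
        """Read a TSV written by `to_tsv` (or any variant,t0,t1,... table).

        The JSON sidecar is used for schedule/N_t/wild-type metadata when
        present; explicit arguments override it.  Without either, times are
        parsed from the column headers (``t0``, ``t1``, ...).
        """
        path = Path(path)
        counts = pd.read_csv(path, sep="\t", index_col="variant")
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            if times is None:
                times = sidecar["times"]
            if read_totals is None:
                read_totals = sidecar.get("read_totals")
            if wild_type == WILD_TYPE_LABEL and sidecar.get("wild_type"):
                wild_type = sidecar["wild_type"]
        if times is None:
            times = [_parse_time_label(c) for c in counts.columns]
        return cls(counts, TimepointSchedule(tuple(times)), read_totals, wild_type)

    def to_hdf(self, path: Union[str, Path], key: str = "counts") -> None:
        """Append this table to an HDF5 store (requires the hdf5 extra)."""
        self.counts.to_hdf(path, key=key)
        meta = pd.DataFrame(
            {"time": self.schedule.times, "read_total": self.read_totals}
        )
        meta.to_hdf(path, key=f"{key}_meta")


def _time_label(t: float) -> str:
    return f"t{t:g}"


def _parse_time_label(label: str) -> float:
    if not label.startswith("t"):
        raise ValueError(f"cannot parse timepoint from column {label!r}")
    return float(label[1:])


@dataclass
class AlignedReplicates:
    """A unified variant index over replicate tables.

    ``missing`` distinguishes a variant absent from a replicate (never
    observed in that library) from an observed zero count.
    """

    variants: pd.Index
    tables: list[VariantCountTable]
    missing: pd.DataFrame  # variants x replicates, True where absent


def align_replicates(tables: Sequence[VariantCountTable]) -> AlignedReplicates:
    """Align replicate count tables on the union of their variants.

    All replicates must share the same `TimepointSchedule`.  Missing
    (variant, replicate) cells are filled with zero counts and flagged.
    """
    if not tables:
        raise ValueError("need at least one table")
    schedule = tables[0].schedule
    for t in tables[1:]:
        if t.schedule != schedule:
            raise ValueError("replicates have incompatible timepoint schedules")
    union = tables[0].variants
    for t in tables[1:]:
        union = union.union(t.variants)
    union = pd.Index(sorted(union))
    missing = pd.DataFrame(
        {i: ~union.isin(t.variants) for i, t in enumerate(tables)}, index=union
    )
    aligned = [
        VariantCountTable(
            t.counts.reindex(union, fill_value=0),
            schedule,
            read_totals=t.read_totals,
            wild_type=t.wild_type,
        )
        for t in tables
    ]
    return AlignedReplicates(union, aligned, missing)
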