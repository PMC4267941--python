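"""Sampling layouts for diel expression time courses.

A layout describes how an expression matrix's columns map onto clock time:
the sampling interval, the length of one day, how many (replicate) days are
appended, and how long the light phase lasts.  The default matches a common
diel design: samples every 3 h from ZT 0 to ZT 21 under 12 h light : 12 h
dark, with two biological replicates appended as two consecutive 24-h days
(16 columns in total).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SamplingLayout:
    """Column layout of a diel expression matrix.

    Parameters
    ----------
    interval_hours:
        Spacing between consecutive samples within a day, in hours.
    day_length_hours:
        Length of one environmental cycle (period of interest), in hours.
    n_days:
        Number of appended days.  Replicate days are concatenated along the
        time axis, so the matrix has ``n_days * points_per_day`` columns.
    light_hours:
        Duration of the light phase; ZT 0 is dawn.  Informational only.
    """

    interval_hours: float = 3.0
    day_length_hours: float = 24.0
    n_days: int = 2
    light_hours: float = 12.0

    def __post_init__(self) -> None:
        if self.interval_hours <= 0 or self.day_length_hours <= 0:
            raise ValueError("interval and day length must be positive")
        if self.n_days < 1:
            raise ValueError("need at least one day")
        ratio = self.day_length_hours / self.interval_hours
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "day_length_hours must be an integer multiple of interval_hours"
            )

    @property
    def points_per_day(self) -> int:
        return int(round(self.day_length_hours / self.interval_hours))

    @property
    def n_points(self) -> int:
        """Total number of samples N across all appended days."""
        return self.n_days * self.points_per_day

    @property
    def total_hours(self) -> float:
        """Time span T covered by the full vector."""
        return self.n_days * self.day_length_hours

    def sample_times(self):
        """Absolute sample times in hours, 0, Δ, 2Δ, … over all days."""
        import numpy as np

        return np.arange(self.n_points) * self.interval_hours

    def zt_of_column(self, j: int) -> float:
        """ZT (hours since dawn) of column ``j``."""
        return (j % self.points_per_day) * self.interval_hours

    def zt_bins(self):
        """The ZT bin labels (0, Δ, 2Δ, …) of one day, in order."""
        return [i * self.interval_hours for i in range(self.points_per_day)]

    def column_labels(self) -> list[str]:
        """TSV column headers of the form ``ZT<h>_day<d>``."""
        labels = []
        for d in range(1, self.n_days + 1):
            for i in range(self.points_per_day):
                zt = i * self.interval_hours
                zt_s = f"{zt:g}"
                labels.append(f"ZT{zt_s}_day{d}")
        return labels


DEFAULT_LAYOUT = SamplingLayout()
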