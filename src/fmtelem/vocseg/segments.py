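"""Vocal-segment data model and Raven-style selection-table I/O.

Selection tables are tab-separated with columns ``Begin Time (s)``,
``End Time (s)``, ``Channel``, ``Crosstalk`` and ``Unsure``; consolidated
tables add ``Bird``, ``Transmitter`` and ``FirstMic`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "VocalSegment",
    "ConsolidatedSegment",
    "read_selection_table",
    "write_selection_table",
    "write_consolidated_table",
    "read_consolidated_table",
]


@dataclass(frozen=True)
class VocalSegment:
    """A transmitter- or microphone-based annotation.

    ``crosstalk`` is 'No' or the transmitter channel of the bird that
    generated the crosstalk; segments tagged ``unsure`` are treated as
    non-vocal noise and excluded from every statistic except the
    uncertainty count.
    """

    source: str
    onset_s: float
    offset_s: float
    crosstalk: str = "No"
    unsure: bool = False

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError(f"segment onset must precede offset: {self}")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlap_s(self, other: "VocalSegment | ConsolidatedSegment") -> float:
        return min(self.offset_s, other.offset_s) - max(self.onset_s, other.onset_s)


@dataclass(frozen=True)
class ConsolidatedSegment:
    """A vocal event merged across transmitter and microphone annotations.

    A non-None ``transmitter`` implies ``bird == transmitter``.
    """

    onset_s: float
    offset_s: float
    bird: str | None
    transmitter: str | None
    firstmic: str | None

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise ValueError(f"segment onset must precede offset: {self}")
        if self.transmitter is not None and self.bird != self.transmitter:
            raise ValueError("a transmitter tag fixes the bird tag")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlap_s(self, other: "VocalSegment | ConsolidatedSegment") -> float:
        return min(self.offset_s, other.offset_s) - max(self.onset_s, other.onset_s)


_COLUMNS = ["Begin Time (s)", "End Time (s)", "Channel", "Crosstalk", "Unsure"]


def write_selection_table(path: str, segments: list[VocalSegment]) -> None:
    df = pd.DataFrame(
        [
            {
                "Begin Time (s)": s.onset_s,
                "End Time (s)": s.offset_s,
                "Channel": s.source,
                "Crosstalk": s.crosstalk,
                "Unsure": "Yes" if s.unsure else "No",
            }
            for s in segments
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_selection_table(path: str) -> list[VocalSegment]:
    df = pd.read_csv(path, sep="\t")
    segments = []
    for _, row in df.iterrows():
        segments.append(
            VocalSegment(
                source=str(row["Channel"]),
                onset_s=float(row["Begin Time (s)"]),
                offset_s=float(row["End Time (s)"]),
                crosstalk=str(row.get("Crosstalk", "No")),
                unsure=str(row.get("Unsure", "No")).lower() in ("yes", "true", "1"),
            )
        )
    return segments


def write_consolidated_table(path: str, segments: list[ConsolidatedSegment]) -> None:
    df = pd.DataFrame(
        [
            {
                "Begin Time (s)": s.onset_s,
                "End Time (s)": s.offset_s,
                "Bird": s.bird if s.bird is not None else "None",
                "Transmitter": s.transmitter if s.transmitter is not None else "None",
                "FirstMic": s.firstmic if s.firstmic is not None else "None",
            }
            for s in segments
        ],
        columns=["Begin Time (s)", "End Time (s)", "Bird", "Transmitter", "FirstMic"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_consolidated_table(path: str) -> list[ConsolidatedSegment]:
    df = pd.read_csv(path, sep="\t")

    def tag(x) -> str | None:
        return None if str(x) == "None" else str(x)

    return [
        ConsolidatedSegment(
            float(row["Begin Time (s)"]),
            float(row["End Time (s)"]),
            tag(row["Bird"]),
            tag(row["Transmitter"]),
            tag(row["FirstMic"]),
        )
        for _, row in df.iterrows()
    ]
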