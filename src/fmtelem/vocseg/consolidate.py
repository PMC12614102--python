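"""Consolidation of transmitter- and microphone-based vocal segments.

Pairing means temporal overlap of at least one spectrogram bin.  The rules:

1. mic segment paired with exactly one transmitter segment -> one
   consolidated segment spanning the union interval, with both tags set;
2. unpaired transmitter segment -> same interval, FirstMic 'None';
3. unpaired mic segment -> same interval, Transmitter 'None', Bird from an
   optional guess table (default 'None');
4. mic segment paired with several transmitter segments -> one consolidated
   segment per transmitter segment, intervals split at transmitter-segment
   boundaries (mic overhang attached to the outermost segments);
5. a transmitter segment paired with several mic segments is treated as an
   annotation error and raises.

Unsure segments and crosstalk transmitter segments are excluded before
pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from fmtelem.vocseg.segments import ConsolidatedSegment, VocalSegment

__all__ = ["VocStats", "consolidate", "voc_statistics"]


def _active(segments: Sequence[VocalSegment], drop_crosstalk: bool) -> list[VocalSegment]:
    out = []
    for s in segments:
        if s.unsure:
            continue
        if drop_crosstalk and s.crosstalk not in ("No", "no", ""):
            continue
        out.append(s)
    return out


def _check_no_overlap_within_source(segments: Sequence[VocalSegment]) -> None:
    by_source: dict[str, list[VocalSegment]] = {}
    for s in segments:
        by_source.setdefault(s.source, []).append(s)
    for source, segs in by_source.items():
        segs = sorted(segs, key=lambda s: s.onset_s)
        for a, b in zip(segs, segs[1:]):
            if b.onset_s < a.offset_s:
                raise ValueError(
                    f"overlapping segments within source {source!r}: {a} / {b}"
                )


def consolidate(
    transmitter_segments: Sequence[VocalSegment],
    mic_segments: Sequence[VocalSegment],
    bin_s: float,
    bird_guess: Mapping[tuple[float, float], str] | None = None,
) -> list[ConsolidatedSegment]:
    """Merge transmitter and microphone annotations into consolidated segments.

    ``bin_s`` is the spectrogram bin duration defining the minimal overlap
    for pairing.  ``bird_guess`` optionally maps an unpaired mic segment's
    ``(onset, offset)`` to a guessed bird.
    """
    if bin_s <= 0:
        raise ValueError("bin duration must be positive")
    trs = _active(transmitter_segments, drop_crosstalk=True)
    mics = _active(mic_segments, drop_crosstalk=False)
    _check_no_overlap_within_source(trs)

    pairs_of_mic: dict[int, list[int]] = {i: [] for i in range(len(mics))}
    pairs_of_tr: dict[int, list[int]] = {j: [] for j in range(len(trs))}
    for i, m in enumerate(mics):
        for j, t in enumerate(trs):
            if m.overlap_s(t) >= bin_s:
                pairs_of_mic[i].append(j)
                pairs_of_tr[j].append(i)
    for j, paired in pairs_of_tr.items():
        if len(paired) > 1:
            raise ValueError(
                f"transmitter segment {trs[j]} paired with multiple microphone segments"
            )

    out: list[ConsolidatedSegment] = []
    for i, m in enumerate(mics):
        paired = sorted(pairs_of_mic[i], key=lambda j: trs[j].onset_s)
        if len(paired) == 1:
            t = trs[paired[0]]
            out.append(
                ConsolidatedSegment(
                    min(m.onset_s, t.onset_s),
                    max(m.offset_s, t.offset_s),
                    bird=t.source,
                    transmitter=t.source,
                    firstmic=m.source,
                )
            )
        elif len(paired) == 0:
            guess = None
            if bird_guess is not None:
                guess = bird_guess.get((m.onset_s, m.offset_s))
            out.append(
                ConsolidatedSegment(m.onset_s, m.offset_s, bird=guess, transmitter=None, firstmic=m.source)
            )
        else:
            # split at transmitter boundaries; mic overhang goes to the
            # outermost transmitter segments
            for k, j in enumerate(paired):
                t = trs[j]
                onset = min(m.onset_s, t.onset_s) if k == 0 else t.onset_s
                offset = max(m.offset_s, t.offset_s) if k == len(paired) - 1 else t.offset_s
                out.append(
                    ConsolidatedSegment(
                        onset, offset, bird=t.source, transmitter=t.source, firstmic=m.source
                    )
                )
    for j, t in enumerate(trs):
        if not pairs_of_tr[j]:
            out.append(
                ConsolidatedSegment(t.onset_s, t.offset_s, bird=t.source, transmitter=t.source, firstmic=None)
            )
    out.sort(key=lambda s: (s.onset_s, s.offset_s))
    return out


@dataclass(frozen=True)
class VocStats:
    """Counts (and percentages of ``n_vocalizations``) per statistic."""

    n_vocalizations: int
    n_missed_transmitter: int
    n_missed_all_mics: int
    n_missed_mic1: int
    n_unassigned: int
    n_overlapping: int
    n_crosstalk: int
    n_uncertain: int

    def percent(self, count: int) -> float:
        return 100.0 * count / self.n_vocalizations if self.n_vocalizations else 0.0

    def as_dict(self) -> dict[str, float]:
        d = {
            "n_vocalizations": self.n_vocalizations,
            "n_missed_transmitter": self.n_missed_transmitter,
            "n_missed_all_mics": self.n_missed_all_mics,
            "n_missed_mic1": self.n_missed_mic1,
            "n_unassigned": self.n_unassigned,
            "n_overlapping": self.n_overlapping,
            "n_crosstalk": self.n_crosstalk,
            "n_uncertain": self.n_uncertain,
        }
        for key in list(d):
            if key not in ("n_vocalizations", "n_uncertain"):
                d[key.replace("n_", "pct_", 1)] = self.percent(d[key])
        return d


def voc_statistics(
    consolidated: Sequence[ConsolidatedSegment],
    raw_transmitter_segments: Sequence[VocalSegment],
    raw_mic_segments: Sequence[VocalSegment],
    mic_order: Sequence[str] = ("Mic1",),
    bin_s: float = 96 / 24414.0625,
) -> VocStats:
    """Summary statistics over a consolidated segmentation.

    ``mic_order[0]`` names the reference microphone for the missed-on-Mic1
    count.  A consolidated segment counts as overlapping when it shares at
    least one spectrogram bin with a segment attributed to a different bird
    (both birds known); both members of such a pair are counted.
    """
    mic1 = mic_order[0] if mic_order else "Mic1"
    n = len(consolidated)
    missed_tr = sum(1 for s in consolidated if s.transmitter is None)
    missed_all = sum(1 for s in consolidated if s.firstmic is None)
    missed_mic1 = sum(1 for s in consolidated if s.firstmic not in (mic1, None))
    unassigned = sum(1 for s in consolidated if s.bird is None)
    overlapping = 0
    for i, s in enumerate(consolidated):
        for k, other in enumerate(consolidated):
            if k == i or s.bird is None or other.bird is None or s.bird == other.bird:
                continue
            if s.overlap_s(other) >= bin_s:
                overlapping += 1
                break
    crosstalk = sum(
        1 for s in raw_transmitter_segments if s.crosstalk not in ("No", "no", "")
    )
    uncertain = sum(1 for s in raw_transmitter_segments if s.unsure) + sum(
        1 for s in raw_mic_segments if s.unsure
    )
    return VocStats(n, missed_tr, missed_all, missed_mic1, unassigned, overlapping, crosstalk, uncertain)
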