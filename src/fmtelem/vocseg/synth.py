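"""Seeded synthetic annotation generator with known ground truth.

The generator plants vocal events per bird, renders them as transmitter- and
microphone-based segments with controllable miss/crosstalk probabilities,
and records the intended consolidated outcome for every event so that
``consolidate`` + ``voc_statistics`` can be verified end to end.

Model (documented for parameter recovery):

* per event the transmitter segment is dropped with probability
  ``miss_probs['transmitter']`` and the mic segment independently with
  ``miss_probs['mic']``; when both draws fire, the mic segment is kept so
  the event stays observable;
* with probability ``miss_probs['mic_shift']`` the mic segment appears on a
  non-first microphone (missed on Mic1);
* events chosen for overlap (probability ``overlap_prob``, needs >= 2
  birds) are placed overlapping an event of another bird; overlapping
  events form a single merged mic segment and their misses are suppressed
  so the ground truth stays well defined;
* with probability ``crosstalk_prob`` a transmitter segment is mirrored on
  another bird's channel tagged as crosstalk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fmtelem.vocseg.segments import ConsolidatedSegment, VocalSegment

__all__ = ["AnnotationGroundTruth", "generate_annotations"]


@dataclass
class AnnotationGroundTruth:
    consolidated: list[ConsolidatedSegment]
    n_events: int
    n_missed_transmitter: int
    n_missed_mic: int
    n_missed_mic1: int
    n_overlapping: int
    n_crosstalk: int
    events: list[tuple[str, float, float]] = field(default_factory=list)


def generate_annotations(
    n_birds: int,
    n_mics: int,
    rates: float | list[float],
    overlap_prob: float = 0.0,
    miss_probs: dict[str, float] | None = None,
    crosstalk_prob: float = 0.0,
    seed: int = 0,
    duration_s: float = 60.0,
    mic_jitter_s: float = 0.01,
    bin_s: float = 0.004,
) -> tuple[list[VocalSegment], list[VocalSegment], AnnotationGroundTruth]:
    """Generate (transmitter_segments, mic_segments, ground_truth).

    ``rates`` is the per-bird vocal event rate (events/s).  Identical seeds
    give identical tables.
    """
    if n_birds < 1 or n_mics < 1:
        raise ValueError("need at least one bird and one microphone")
    miss_probs = dict(miss_probs or {})
    p_tr = float(miss_probs.get("transmitter", 0.0))
    p_mic = float(miss_probs.get("mic", 0.0))
    p_shift = float(miss_probs.get("mic_shift", 0.0))
    if overlap_prob > 0 and n_birds < 2:
        raise ValueError("overlaps need at least two birds")
    rng = np.random.default_rng(seed)
    birds = [f"bird{i + 1}" for i in range(n_birds)]
    mics = [f"Mic{i + 1}" for i in range(n_mics)]
    rate_list = [float(rates)] * n_birds if np.isscalar(rates) else [float(r) for r in rates]

    # plant events; a fraction is forced to overlap an event of another bird
    events: list[tuple[str, float, float, bool]] = []  # (bird, on, off, overlapped)
    for b, bird in enumerate(birds):
        t = 0.0
        while True:
            t += rng.exponential(1.0 / rate_list[b]) + 0.05
            dur = rng.uniform(0.05, 0.3)
            if t + dur > duration_s:
                break
            events.append((bird, t, t + dur, False))
            t += dur
    events.sort(key=lambda e: e[1])

    extra: list[tuple[str, float, float, bool]] = []
    flagged: list[tuple[str, float, float, bool]] = []
    for bird, on, off, _ in events:
        if overlap_prob > 0 and rng.random() < overlap_prob:
            other = rng.choice([b for b in birds if b != bird])
            dur = rng.uniform(0.05, 0.3)
            shift = rng.uniform(-0.5, 0.5) * min(dur, off - on)
            o_on = max(on + shift, 0.0)
            o_off = min(o_on + dur, duration_s)
            if o_off - o_on > 0.02 and min(o_off, off) - max(o_on, on) > 0.01:
                extra.append((other, o_on, o_off, True))
                flagged.append((bird, on, off, True))
                continue
        flagged.append((bird, on, off, False))
    all_events = flagged + extra
    all_events.sort(key=lambda e: e[1])

    # discard events that collide within one bird (keeps sources overlap-free)
    per_bird_last: dict[str, float] = {}
    kept: list[tuple[str, float, float, bool]] = []
    for bird, on, off, ov in all_events:
        if on <= per_bird_last.get(bird, -1.0):
            continue
        kept.append((bird, on, off, ov))
        per_bird_last[bird] = off

    # group events into overlap components (across birds)
    kept.sort(key=lambda e: e[1])
    components: list[list[tuple[str, float, float, bool]]] = []
    comp_end = -1.0
    for ev in kept:
        if components and ev[1] < comp_end:
            components[-1].append(ev)
            comp_end = max(comp_end, ev[2])
        else:
            components.append([ev])
            comp_end = ev[2]

    tr_segments: list[VocalSegment] = []
    mic_segments: list[VocalSegment] = []
    gt_consolidated: list[ConsolidatedSegment] = []
    n_missed_tr = n_missed_mic = n_missed_mic1 = n_overlap = n_crosstalk = 0

    for comp in components:
        multi = len(comp) > 1
        # mic boundaries jitter inward so mic segments never leak into
        # neighbouring components
        jit = rng.uniform(0, mic_jitter_s, size=2)
        mic_on = min(e[1] for e in comp) + jit[0]
        mic_off = max(e[2] for e in comp) - jit[1]
        if mic_off - mic_on < 0.03:
            mic_on, mic_off = min(e[1] for e in comp), max(e[2] for e in comp)
        if multi:
            # misses suppressed: all transmitter segments and the merged mic
            # segment are present
            mic_name = mics[0] if (p_shift == 0 or rng.random() >= p_shift or n_mics < 2) else str(
                rng.choice(mics[1:])
            )
            if mic_name != mics[0]:
                n_missed_mic1 += len(comp)
            mic_segments.append(VocalSegment(mic_name, mic_on, mic_off))
            ordered = sorted(comp, key=lambda e: e[1])
            for k, (bird, on, off, _) in enumerate(ordered):
                tr_segments.append(VocalSegment(bird, on, off))
                g_on = min(mic_on, on) if k == 0 else on
                g_off = max(mic_off, off) if k == len(ordered) - 1 else off
                gt_consolidated.append(ConsolidatedSegment(g_on, g_off, bird, bird, mic_name))
            continue
        bird, on, off, _ = comp[0]
        drop_tr = rng.random() < p_tr
        drop_mic = rng.random() < p_mic
        if drop_tr and drop_mic:
            drop_mic = False  # keep the event observable
        shift_mic = (not drop_mic) and n_mics >= 2 and rng.random() < p_shift
        mic_name = str(rng.choice(mics[1:])) if shift_mic else mics[0]
        if not drop_tr:
            tr_segments.append(VocalSegment(bird, on, off))
        else:
            n_missed_tr += 1
        if not drop_mic:
            mic_segments.append(VocalSegment(mic_name, mic_on, mic_off))
            if shift_mic:
                n_missed_mic1 += 1
        else:
            n_missed_mic += 1
        if drop_tr:
            gt_consolidated.append(ConsolidatedSegment(mic_on, mic_off, None, None, mic_name))
        elif drop_mic:
            gt_consolidated.append(ConsolidatedSegment(on, off, bird, bird, None))
        else:
            gt_consolidated.append(
                ConsolidatedSegment(min(on, mic_on), max(off, mic_off), bird, bird, mic_name)
            )
        if n_birds >= 2 and not drop_tr and rng.random() < crosstalk_prob:
            other = str(rng.choice([b for b in birds if b != bird]))
            tr_segments.append(VocalSegment(other, on, off, crosstalk=bird))
            n_crosstalk += 1

    # crosstalk mirrors may collide with genuine segments of the same
    # channel; drop the mirrors that do (the generator's invariant is that
    # genuine segments never overlap within a source)
    cleaned: list[VocalSegment] = []
    for s in tr_segments:
        if s.crosstalk != "No":
            clash = any(
                o.source == s.source and o is not s and s.overlap_s(o) > 0 for o in tr_segments
            )
            if clash:
                n_crosstalk -= 1
                continue
        cleaned.append(s)
    tr_segments = cleaned

    tr_segments.sort(key=lambda s: (s.source, s.onset_s))
    mic_segments.sort(key=lambda s: (s.source, s.onset_s))
    gt_consolidated.sort(key=lambda s: (s.onset_s, s.offset_s))
    # intended overlap count: brute force over the intended consolidated
    # intervals (>= one spectrogram bin with a different, known bird)
    for i, s in enumerate(gt_consolidated):
        for k, other in enumerate(gt_consolidated):
            if k == i or s.bird is None or other.bird is None or s.bird == other.bird:
                continue
            if s.overlap_s(other) >= bin_s:
                n_overlap += 1
                break
    gt = AnnotationGroundTruth(
        consolidated=gt_consolidated,
        n_events=len(gt_consolidated),
        n_missed_transmitter=n_missed_tr,
        n_missed_mic=n_missed_mic,
        n_missed_mic1=n_missed_mic1,
        n_overlapping=n_overlap,
        n_crosstalk=n_crosstalk,
        events=[(b, on, off) for b, on, off, _ in kept],
    )
    return tr_segments, mic_segments, gt
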