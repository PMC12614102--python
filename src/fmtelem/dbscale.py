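"""Decibel bookkeeping for frequency-modulation amplitudes."""

import math

__all__ = ["db_re", "db_re_1khz"]


def db_re(amplitude: float, reference: float) -> float:
    """Express an amplitude ratio in dB: ``20*log10(amplitude/reference)``.

    Both arguments must be positive and in the same units.
    """
    if amplitude <= 0 or reference <= 0:
        raise ValueError("amplitude and reference must be positive")
    return 20.0 * math.log10(amplitude / reference)


def db_re_1khz(amplitude_hz: float) -> float:
    """FM amplitude in dB relative to the 1 kHz reference deviation.

    A 2.5 MHz excursion maps to ~68 dB re 1 kHz; a 3.4 kHz vocal
    deviation maps to ~11 dB re 1 kHz.
    """
    return db_re(amplitude_hz, 1e3)
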