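"""Canonical EEG feature streams.

Every session is summarized by 10 numeric streams: eight rhythm-band powers
(delta through high-gamma, as reported by a single-channel consumer EEG
headset) plus the two derived cognitive indices, attention and meditation.
The fixed canonical order below defines the column layout of every matrix
in the package.
"""

from __future__ import annotations

import re
from enum import Enum


class Moment(str, Enum):
    """Therapy moment a session belongs to."""

    BEFORE = "Before"
    DURING = "During"
    AFTER = "After"

    @classmethod
    def parse(cls, text: str) -> "Moment":
        try:
            return _MOMENT_LOOKUP[text.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown therapy moment: {text!r}") from None


_MOMENT_LOOKUP = {m.value.lower(): m for m in Moment}

MOMENTS = (Moment.BEFORE, Moment.DURING, Moment.AFTER)


class Stream(str, Enum):
    """The 10 canonical feature streams, in fixed order."""

    DELTA = "delta"
    THETA = "theta"
    ALPHA_LOW = "alpha_low"
    ALPHA_HIGH = "alpha_high"
    BETA_LOW = "beta_low"
    BETA_HIGH = "beta_high"
    GAMMA_LOW = "gamma_low"
    GAMMA_HIGH = "gamma_high"
    ATTENTION = "attention"
    MEDITATION = "meditation"


STREAMS: tuple[Stream, ...] = tuple(Stream)
STREAM_NAMES: tuple[str, ...] = tuple(s.value for s in STREAMS)
N_STREAMS = len(STREAMS)

#: The eight rhythm bands (excludes the derived attention/meditation indices).
BANDS: tuple[Stream, ...] = STREAMS[:8]
BAND_NAMES: tuple[str, ...] = tuple(s.value for s in BANDS)

#: Nominal frequency ranges (Hz) of the rhythm bands; the cognitive indices
#: are unitless derived quantities and carry no band range.
BAND_RANGES_HZ: dict[Stream, tuple[float, float]] = {
    Stream.DELTA: (0.5, 2.75),
    Stream.THETA: (3.5, 6.75),
    Stream.ALPHA_LOW: (7.5, 9.25),
    Stream.ALPHA_HIGH: (10.0, 11.75),
    Stream.BETA_LOW: (13.0, 16.75),
    Stream.BETA_HIGH: (18.0, 29.75),
    Stream.GAMMA_LOW: (31.0, 39.75),
    Stream.GAMMA_HIGH: (41.0, 49.75),
}

# Header aliases accepted when parsing recording files.  Keys are normalized
# by _normalize_header (lower-case, separators stripped).
_ALIASES: dict[str, Stream] = {}


def _register(stream: Stream, *names: str) -> None:
    for n in names:
        _ALIASES[n] = stream


_register(Stream.DELTA, "delta", "δ")
_register(Stream.THETA, "theta", "θ")
_register(Stream.ALPHA_LOW, "alphalow", "lowalpha", "alpha1", "α↓", "αlow")
_register(Stream.ALPHA_HIGH, "alphahigh", "highalpha", "alpha2", "α↑", "αhigh")
_register(Stream.BETA_LOW, "betalow", "lowbeta", "beta1", "β↓", "βlow")
_register(Stream.BETA_HIGH, "betahigh", "highbeta", "beta2", "β↑", "βhigh")
_register(Stream.GAMMA_LOW, "gammalow", "lowgamma", "gamma1", "γ↓", "γlow")
_register(Stream.GAMMA_HIGH, "gammahigh", "highgamma", "midgamma", "gamma2", "γ↑", "γhigh")
_register(Stream.ATTENTION, "attention", "att")
_register(Stream.MEDITATION, "meditation", "med")

_SEPARATORS = re.compile(r"[\s_\-]+")


def _normalize_header(token: str) -> str:
    return _SEPARATORS.sub("", token.strip().lower())


def resolve_stream(token: str) -> Stream | None:
    """Map a header token to its canonical stream, or None if unrecognized."""
    return _ALIASES.get(_normalize_header(token))
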