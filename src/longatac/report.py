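"""Small reporting helpers shared by the CLI summaries."""

from __future__ import annotations


def percent(numerator: int, denominator: int, digits: int = 1) -> float:
    """A count ratio as a percentage, rounded to ``digits`` decimals.

    The convention used everywhere the pipeline reports a fraction of a
    count (overlapping peaks, doublet cells, validated calls, ...).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, digits)


def fraction(numerator: int, denominator: int, digits: int = 4) -> float:
    """A count ratio rounded to ``digits`` decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(numerator / denominator, digits)
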