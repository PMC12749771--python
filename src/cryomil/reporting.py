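"""Small reporting helpers for count tables.

Used e.g. for pathologist adjudication tables, where expert-reviewed top
predictive patches are tallied into categories (malignant / uncertain /
benign) and reported as percentages of the total.
"""

from __future__ import annotations

from .errors import ConfigurationError, DegenerateInputError


def fraction_breakdown(counts: dict[str, int]) -> dict[str, float]:
    """Percentages of each category out of the summed counts."""
    if not counts:
        raise DegenerateInputError("empty count table")
    for k, v in counts.items():
        if v < 0:
            raise ConfigurationError(f"count for '{k}' is negative")
    total = sum(counts.values())
    if total == 0:
        raise DegenerateInputError("all counts are zero")
    return {k: 100.0 * v / total for k, v in counts.items()}


def percent_of(numerator: int, denominator: int) -> float:
    """A single count ratio as a percentage."""
    if denominator <= 0:
        raise DegenerateInputError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ConfigurationError("numerator must lie in [0, denominator]")
    return 100.0 * numerator / denominator
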