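"""SuperSelective primer strategy notation.

A SuperSelective primer is written ``anchor-bridge/intervening-f:1:t``,
e.g. ``21–7/8–5:1:1``: a 21-nt anchor, a 7-nt bridge on the primer side of
the bubble, 8 nt of intervening template on the template side, and a foot
of 5 matched bases, the interrogated base, then ``t`` (0 or 1) further
matched bases 3' of it.  With ``t == 1`` the interrogated nucleotide is the
second-last base of the primer; with ``t == 0`` it is the last.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import StrategyParseError, StrategyError

# hyphen, en-dash and em-dash all accepted as segment separators
_SEP = r"[-–—]"
_PATTERN = re.compile(
    rf"^\s*(\S+?)\s*{_SEP}\s*(\S+?)\s*/\s*(\S+?)\s*{_SEP}\s*(\S+?)\s*:\s*(\S+?)\s*:\s*(\S+?)\s*$"
)

#: The three foot layouts used for allele discrimination:
#: (foot_5p, foot_3p) pairs — 4:1:1, 5:1:1 and 6:1:0.
FOOT_STRATEGIES: tuple[tuple[int, int], ...] = ((4, 1), (5, 1), (6, 0))


@dataclass(frozen=True)
class StrategySpec:
    """Parsed ``anchor–bridge/intervening–f:1:t`` design notation."""

    anchor_len: int
    bridge_len: int
    intervening_len: int
    foot_5p: int
    foot_3p: int

    def __post_init__(self) -> None:
        if self.anchor_len < 10:
            raise StrategyError(f"anchor_len must be >= 10, got {self.anchor_len}")
        if self.bridge_len < 1:
            raise StrategyError(f"bridge_len must be >= 1, got {self.bridge_len}")
        if self.intervening_len < 1:
            raise StrategyError(
                f"intervening_len must be >= 1, got {self.intervening_len}"
            )
        if self.foot_5p < 3:
            raise StrategyError(f"foot_5p must be >= 3, got {self.foot_5p}")
        if self.foot_3p not in (0, 1):
            raise StrategyError(f"foot_3p must be 0 or 1, got {self.foot_3p}")

    @property
    def foot_len(self) -> int:
        """Total foot length: matched 5' bases + interrogated base + 3' bases."""
        return self.foot_5p + 1 + self.foot_3p

    @property
    def interrogated_index(self) -> int:
        """0-based index of the interrogated base within the foot."""
        return self.foot_5p

    def notation(self) -> str:
        """Canonical notation, using en-dashes."""
        return (
            f"{self.anchor_len}–{self.bridge_len}/"
            f"{self.intervening_len}–{self.foot_5p}:1:{self.foot_3p}"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.notation()


def _int_field(token: str, name: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise StrategyParseError(
            f"strategy field {name} is not an integer: {token!r}"
        ) from None


def parse_strategy(notation: str) -> StrategySpec:
    """Parse ``"21–7/8–5:1:1"`` (hyphen/en-dash/em-dash separators accepted).

    Raises
    ------
    StrategyParseError
        If the notation is malformed, names the offending token.
    StrategyError
        If the integers violate strategy invariants (e.g. ``t`` not 0/1).
    """
    m = _PATTERN.match(notation)
    if m is None:
        raise StrategyParseError(
            f"cannot parse strategy notation {notation!r}; "
            "expected anchor-bridge/intervening-f:1:t"
        )
    anchor = _int_field(m.group(1), "anchor_len")
    bridge = _int_field(m.group(2), "bridge_len")
    intervening = _int_field(m.group(3), "intervening_len")
    foot_5p = _int_field(m.group(4), "foot_5p")
    mid = _int_field(m.group(5), "foot_interrogated")
    foot_3p = _int_field(m.group(6), "foot_3p")
    if mid != 1:
        raise StrategyParseError(
            f"middle foot field must be 1 (the interrogated base), got {mid}"
        )
    if foot_3p not in (0, 1):
        raise StrategyParseError(f"foot_3p must be 0 or 1, got {foot_3p}")
    return StrategySpec(anchor, bridge, intervening, foot_5p, foot_3p)


def format_strategy(spec: StrategySpec) -> str:
    """Canonical en-dash notation for ``spec`` (inverse of :func:`parse_strategy`)."""
    return spec.notation()
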