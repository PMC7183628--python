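"""EEG frequency-band definitions.

Bands are half-open intervals ``[lo, hi)`` in Hz so that the contiguous
printed edges (3, 8, 12, 16 Hz) are unambiguous.  The default set is the
clinical one used throughout the package: beta 16-32, sigma 12-16,
alpha 8-12, theta 3-8, delta 0.25-3 Hz.
"""

from __future__ import annotations

from collections.abc import Mapping

from .errors import InvalidParameterError


class BandSet(Mapping):
    """Ordered, non-overlapping named frequency intervals (Hz)."""

    def __init__(self, bands: dict[str, tuple[float, float]]):
        items = []
        for name, (lo, hi) in bands.items():
            lo, hi = float(lo), float(hi)
            if not (0 <= lo < hi):
                raise InvalidParameterError(f"band {name!r}: need 0 <= lo < hi, got [{lo}, {hi})")
            items.append((name, (lo, hi)))
        for name_a, (lo_a, hi_a) in items:
            for name_b, (lo_b, hi_b) in items:
                if name_a != name_b and lo_a < hi_b and lo_b < hi_a:
                    raise InvalidParameterError(f"bands {name_a!r} and {name_b!r} overlap")
        self._bands = dict(items)

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self._bands[name]

    def __iter__(self):
        return iter(self._bands)

    def __len__(self) -> int:
        return len(self._bands)

    @property
    def max_edge(self) -> float:
        return max(hi for _, hi in self._bands.values())


#: Canonical EEG bands (order: fast to slow, matching the reporting tables).
DEFAULT_BANDS = BandSet({
    "beta": (16.0, 32.0),
    "sigma": (12.0, 16.0),
    "alpha": (8.0, 12.0),
    "theta": (3.0, 8.0),
    "delta": (0.25, 3.0),
})
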