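"""Discrete time-bin schemes for biochronological analysis.

A scheme is an ordered sequence of named, contiguous, non-overlapping age
bins (older bound > younger bound, in Ma).  Ordinals increase towards the
present, so "previous" means the older neighbour and "next" the younger one.
The default scheme covers the European Neogene/Quaternary land-mammal zones
(MN1..MN17 plus the informal MQ18/MQ19) from 23.0 to 0.01 Ma, with MN7 and
MN8 combined, following standard published correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd


@dataclass(frozen=True)
class TimeBin:
    """One named age bin with bounds in Ma (older > younger)."""

    name: str
    older_bound: float
    younger_bound: float
    ordinal: int

    def __post_init__(self) -> None:
        if not (self.older_bound > self.younger_bound > 0):
            raise ValueError(
                f"bin {self.name!r}: need older_bound > younger_bound > 0, "
                f"got ({self.older_bound}, {self.younger_bound})"
            )

    @property
    def duration_myr(self) -> float:
        return self.older_bound - self.younger_bound

    @property
    def midpoint_ma(self) -> float:
        return 0.5 * (self.older_bound + self.younger_bound)


class TimeBinScheme:
    """Ordered collection of :class:`TimeBin` with name/ordinal lookup."""

    def __init__(self, bins: list[TimeBin]):
        if not bins:
            raise ValueError("empty bin scheme")
        bins = sorted(bins, key=lambda b: b.ordinal)
        for a, b in zip(bins, bins[1:]):
            if b.ordinal != a.ordinal + 1:
                raise ValueError("ordinals must be consecutive integers")
            if b.older_bound > a.younger_bound + 1e-9:
                raise ValueError(
                    f"bins {a.name} and {b.name} overlap or are out of age order"
                )
        self._bins = bins
        self._by_name = {b.name: b for b in bins}
        if len(self._by_name) != len(bins):
            raise ValueError("duplicate bin names")

    def __len__(self) -> int:
        return len(self._bins)

    def __iter__(self) -> Iterator[TimeBin]:
        return iter(self._bins)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> TimeBin:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [b.name for b in self._bins]

    def by_ordinal(self, ordinal: int) -> TimeBin:
        b = self._bins[ordinal - self._bins[0].ordinal]
        assert b.ordinal == ordinal
        return b

    def ordinal(self, name: str) -> int:
        return self._by_name[name].ordinal

    def previous(self, name: str) -> TimeBin | None:
        """The older neighbour, or None at the start of the scheme."""
        o = self.ordinal(name)
        if o == self._bins[0].ordinal:
            return None
        return self.by_ordinal(o - 1)

    def next(self, name: str) -> TimeBin | None:
        """The younger neighbour, or None at the end of the scheme."""
        o = self.ordinal(name)
        if o == self._bins[-1].ordinal:
            return None
        return self.by_ordinal(o + 1)

    # ---- I/O -------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeBinScheme":
        """Read a scheme from CSV with columns name, older, younger, ordinal."""
        df = pd.read_csv(path)
        required = {"name", "older", "younger", "ordinal"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"bin-scheme CSV missing columns: {sorted(missing)}")
        return cls(
            [
                TimeBin(str(r.name), float(r.older), float(r.younger), int(r.ordinal))
                for r in df.itertuples(index=False)
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "name": [b.name for b in self._bins],
                "older": [b.older_bound for b in self._bins],
                "younger": [b.younger_bound for b in self._bins],
                "ordinal": [b.ordinal for b in self._bins],
            }
        ).to_csv(path, index=False)

    @classmethod
    def default_mn_mq(cls) -> "TimeBinScheme":
        """The bundled MN/MQ scheme (23.0 to 0.01 Ma; not authoritative)."""
        with resources.as_file(
            resources.files("fossilhotspots") / "schemes" / "mn_mq.csv"
        ) as p:
            return cls.from_csv(p)

    @classmethod
    def uniform(cls, n_bins: int, duration_myr: float = 1.0,
                prefix: str = "B") -> "TimeBinScheme":
        """Equal-duration synthetic scheme ending at the present: B1 oldest."""
        bins = []
        for i in range(n_bins):
            older = (n_bins - i) * duration_myr
            bins.append(TimeBin(f"{prefix}{i + 1}", older, older - duration_myr
                                if i < n_bins - 1 else max(older - duration_myr, 0.01),
                                i + 1))
        # keep the youngest bound strictly positive
        return cls(bins)
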