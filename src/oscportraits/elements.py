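"""Indexing of the 48 oscillatory elements and the band/epoch conventions.

An *oscillatory element* is the single-trial mean log-normalized power at one
(cortical region, movement phase, frequency band) triple.  Four regions
(independent components IC1..IC4: frontal medial, parietal medial, left and
right sensorimotor), three movement phases (Pre, During, Post) and four
canonical frequency bands (theta, alpha, beta, gamma) give the 48-element
*oscillatory portrait* of a trial.

The column order is frozen here once and exported with every table: region-
major, then epoch, then band (IC1_Pre_theta, IC1_Pre_alpha, ...,
IC4_Post_gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

REGIONS: tuple[str, ...] = ("IC1", "IC2", "IC3", "IC4")
EPOCHS: tuple[str, ...] = ("Pre", "During", "Post")
BANDS: tuple[str, ...] = ("theta", "alpha", "beta", "gamma")

#: Band edges in Hz, inclusive on both sides on the analysis frequency grid.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (9.0, 12.0),
    "beta": (13.0, 35.0),
    "gamma": (36.0, 60.0),
}

N_ELEMENTS = len(REGIONS) * len(EPOCHS) * len(BANDS)

#: The six trial categories: NR (no rotation), RS (rotation with strategy),
#: Ct (unexpected rotation onset) and AR (after rotation removal), each split
#: by target success (Hit/Miss); Ct and AR occur only as Miss.
CATEGORIES: tuple[str, ...] = (
    "NR-Hit",
    "NR-Miss",
    "RS-Hit",
    "RS-Miss",
    "Ct-Miss",
    "AR-Miss",
)

HIT_CATEGORIES: frozenset[str] = frozenset(c for c in CATEGORIES if c.endswith("Hit"))

#: Metadata columns preceding the 48 element columns in a trial table.
META_COLUMNS: tuple[str, ...] = ("subject", "category", "error", "duration")


@dataclass(frozen=True)
class ElementIndex:
    """One (region, epoch, band) triple and its frozen column position."""

    region: str
    epoch: str
    band: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.epoch not in EPOCHS:
            raise ValueError(f"unknown epoch {self.epoch!r}")
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")

    @property
    def column(self) -> int:
        """0-based position in the frozen region-major ordering."""
        return (
            REGIONS.index(self.region) * len(EPOCHS) * len(BANDS)
            + EPOCHS.index(self.epoch) * len(BANDS)
            + BANDS.index(self.band)
        )

    @property
    def name(self) -> str:
        return f"{self.region}_{self.epoch}_{self.band}"

    @classmethod
    def from_column(cls, column: int) -> "ElementIndex":
        if not 0 <= column < N_ELEMENTS:
            raise ValueError(f"column must be in [0, {N_ELEMENTS})")
        r, rest = divmod(column, len(EPOCHS) * len(BANDS))
        e, b = divmod(rest, len(BANDS))
        return cls(REGIONS[r], EPOCHS[e], BANDS[b])

    @classmethod
    def from_name(cls, name: str) -> "ElementIndex":
        try:
            region, epoch, band = name.split("_")
        except ValueError:
            raise ValueError(f"element name {name!r} is not REGION_EPOCH_BAND") from None
        return cls(region, epoch, band)


def element_index() -> list[ElementIndex]:
    """All 48 elements in frozen column order."""
    return [
        ElementIndex(r, e, b)
        for r in REGIONS
        for e in EPOCHS
        for b in BANDS
    ]


def element_columns() -> list[str]:
    """The 48 element column names in frozen order."""
    return [ix.name for ix in element_index()]


def element_labels(axis: str) -> list[str]:
    """Per-element label along one homophily axis.

    ``axis`` is ``"spatial"`` (region), ``"spectral"`` (band) or
    ``"temporal"`` (epoch); returns the 48 labels in column order.
    """
    attr = {"spatial": "region", "spectral": "band", "temporal": "epoch"}
    if axis not in attr:
        raise ValueError(f"axis must be one of {sorted(attr)}, got {axis!r}")
    return [getattr(ix, attr[axis]) for ix in element_index()]


@dataclass(frozen=True)
class BandEpochSpec:
    """Frequency-band edges (Hz) and movement-phase windows.

    Epoch windows are defined relative to movement onset/offset markers:
    Pre = [-1.5 s, onset), During = [onset, offset], Post = (offset,
    offset + 1.5 s].  Band edges are inclusive on the frequency grid; the
    printed bands abut at integer Hz nowhere on a 0.5-Hz grid except via the
    convention that a shared edge belongs to the lower band.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BAND_EDGES)
    )
    pre_margin: float = 1.5
    post_margin: float = 1.5

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if lo >= hi:
                raise ValueError(f"band {name}: low edge {lo} >= high edge {hi}")
        if self.pre_margin <= 0 or self.post_margin <= 0:
            raise ValueError("epoch margins must be positive")

    def band_mask(self, freqs, band: str):
        import numpy as np

        lo, hi = self.bands[band]
        f = np.asarray(freqs, dtype=float)
        return (f >= lo) & (f <= hi)

    def epoch_mask(self, times, epoch: str, onset: float, offset: float):
        import numpy as np

        if offset < onset:
            raise ValueError(f"offset {offset} precedes onset {onset}")
        t = np.asarray(times, dtype=float)
        if epoch == "Pre":
            return (t >= onset - self.pre_margin) & (t < onset)
        if epoch == "During":
            return (t >= onset) & (t <= offset)
        if epoch == "Post":
            return (t > offset) & (t <= offset + self.post_margin)
        raise ValueError(f"unknown epoch {epoch!r}")
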