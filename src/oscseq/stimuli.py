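"""Stimulus sequences and their rendering into per-channel input streams.

Two stimulus families are supported:

* **Unimodal** sequences of five items, each a horizontally (``H``) or
  vertically (``V``) oriented Gabor patch rendered to a small
  black/white/background pixel grid.  Every pixel is one input channel.
* **Crossmodal** sequences of four items, each either a visual bright
  disc in the upper/lower half of the display or a high/low pitched
  beep.  Visual items drive the pixel channels; auditory items drive a
  single extra auditory channel.

Time base: one time step is one stimulus-onset slot.  Every item is
preceded by a blank slot, so an item (blank + stimulus) spans two
steps and a five-item sequence spans ten.  Blank slots carry the
"no input" symbol ``0`` on every channel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import pi, sqrt

import numpy as np

# input-symbol codes (0 is always "no input")
BLACK = 1
WHITE = 2
BRIGHT = 1
PITCH_LOW = 1
PITCH_HIGH = 2

UNIMODAL_LABELS = ("H", "V")
UNIMODAL_LENGTH = 5
CROSSMODAL_LENGTH = 4

__all__ = [
    "BLACK", "WHITE", "BRIGHT", "PITCH_LOW", "PITCH_HIGH",
    "UnimodalSequence", "CrossmodalSequence", "StreamBundle",
    "enumerate_unimodal", "enumerate_crossmodal",
    "render_gabor", "render_disc",
    "build_streams", "make_test_item", "sequence_entropy",
]


@dataclass(frozen=True)
class UnimodalSequence:
    """Five-item sequence of Gabor orientations, e.g. ``-H-V-V-V-V``.

    The binary code maps ``H`` to bit 0 and ``V`` to bit 1, most
    significant bit first, so codes run 0 (``HHHHH``) to 31
    (``VVVVV``).
    """

    items: tuple

    def __post_init__(self):
        if len(self.items) != UNIMODAL_LENGTH:
            raise ValueError(f"unimodal sequences have {UNIMODAL_LENGTH} items")
        if any(it not in UNIMODAL_LABELS for it in self.items):
            raise ValueError(f"items must be in {UNIMODAL_LABELS}")

    @property
    def code(self) -> int:
        c = 0
        for it in self.items:
            c = (c << 1) | (it == "V")
        return c

    @classmethod
    def from_code(cls, code: int) -> "UnimodalSequence":
        if not 0 <= code < 2 ** UNIMODAL_LENGTH:
            raise ValueError("code must be in [0, 31]")
        bits = format(code, f"0{UNIMODAL_LENGTH}b")
        return cls(tuple("V" if b == "1" else "H" for b in bits))

    @classmethod
    def from_string(cls, text: str) -> "UnimodalSequence":
        """Parse compact form like ``-H-V-V-V-V`` (leading dash optional)."""
        return cls(tuple(p for p in text.strip().split("-") if p))

    def __str__(self) -> str:
        return "-" + "-".join(self.items)

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class CrossmodalSequence:
    """Four-item sequence of (modality, level) pairs, e.g. ``AH-VL-VH-VH``.

    Modality is visual (``V``) or auditory (``A``); the shared feature
    level is high (``H``) or low (``L``).  Strictly unimodal sequences
    (all-visual or all-auditory) are excluded by the enumerator but can
    still be constructed explicitly for degenerate runs.
    """

    items: tuple  # of (modality, level) pairs

    def __post_init__(self):
        if len(self.items) != CROSSMODAL_LENGTH:
            raise ValueError(f"crossmodal sequences have {CROSSMODAL_LENGTH} items")
        for m, l in self.items:
            if m not in ("V", "A") or l not in ("H", "L"):
                raise ValueError(f"bad item {(m, l)!r}")

    @property
    def is_strictly_unimodal(self) -> bool:
        mods = {m for m, _ in self.items}
        return len(mods) == 1

    @classmethod
    def from_string(cls, text: str) -> "CrossmodalSequence":
        parts = [p for p in text.strip().split("-") if p]
        return cls(tuple((p[0], p[1]) for p in parts))

    def __str__(self) -> str:
        return "-".join(m + l for m, l in self.items)

    def __len__(self) -> int:
        return len(self.items)


def enumerate_unimodal() -> list:
    """All 32 five-item H/V sequences, ordered by binary code."""
    return [UnimodalSequence.from_code(c) for c in range(2 ** UNIMODAL_LENGTH)]


def enumerate_crossmodal() -> list:
    """All 224 truly crossmodal four-item sequences.

    From the 256 combinations of modality (V/A) and level (H/L) over
    four items, the 2 * 16 strictly unimodal ones are excluded.
    """
    out = []
    for combo in itertools.product(
        [("V", "H"), ("V", "L"), ("A", "H"), ("A", "L")],
        repeat=CROSSMODAL_LENGTH,
    ):
        seq = CrossmodalSequence(tuple(combo))
        if not seq.is_strictly_unimodal:
            out.append(seq)
    return out


def _grid_coords(size: int):
    """Pixel-center coordinates relative to the grid center."""
    c = np.arange(size) + 0.5 - size / 2.0
    return c


def render_gabor(orientation: str, size: int = 20) -> np.ndarray:
    """Render an oriented grating as a binary pixel frame.

    The stimulus is a square-wave reduction of a sinusoidal grating:
    0.5 cycles per degree over a 10-degree aperture, i.e. five cycles
    across the grid, thresholded at its mean into black/white.  Pixels
    outside a centered circular aperture are background (``0``).  The
    horizontal and vertical renderings are transposes of one another,
    which induces exactly five pixel classes over the (H, V) frame
    pair: background, black-in-both, white-in-both, and the two
    alternating classes.
    """
    if orientation not in UNIMODAL_LABELS:
        raise ValueError("orientation must be 'H' or 'V'")
    c = _grid_coords(size)
    period = size / 5.0
    g = np.sin(2 * pi * c / period)
    stripe = np.where(g >= 0, WHITE, BLACK).astype(np.int64)
    if orientation == "H":
        # horizontal stripes: value varies along the row (y) axis
        frame = np.tile(stripe[:, None], (1, size))
    else:
        frame = np.tile(stripe[None, :], (size, 1))
    yy, xx = np.meshgrid(c, c, indexing="ij")
    frame[yy ** 2 + xx ** 2 > (size / 2.0) ** 2] = 0
    return frame


def render_disc(level: str, size: int = 20, geometry: str = "disjoint") -> np.ndarray:
    """Render a bright disc above (``H``) or below (``L``) the midline.

    ``geometry="disjoint"`` (default) places non-overlapping discs of
    radius ``0.225 * size`` centered at ``+-size/4`` from the midline,
    so no pixel is bright in both frames and neither disc crosses the
    midline.  ``geometry="overlap"`` uses larger discs of radius
    ``0.3 * size`` centered at ``+-size/8``, which share a band of
    pixels around the midline ("bright in both" channels exist).
    """
    if level not in ("H", "L"):
        raise ValueError("level must be 'H' or 'L'")
    if geometry == "disjoint":
        cy0, r = size / 4.0, 0.225 * size
    elif geometry == "overlap":
        cy0, r = size / 8.0, 0.3 * size
    else:
        raise ValueError("geometry must be 'disjoint' or 'overlap'")
    c = _grid_coords(size)
    yy, xx = np.meshgrid(c, c, indexing="ij")
    # grid row 0 is the top of the display -> positive display-y is -yy
    cy = cy0 if level == "H" else -cy0
    frame = np.zeros((size, size), dtype=np.int64)
    frame[(-yy - cy) ** 2 + xx ** 2 <= r ** 2] = BRIGHT
    return frame


@dataclass
class StreamBundle:
    """Per-channel symbol streams for one trial.

    ``symbols`` has shape ``(n_channels, n_steps)``; entry ``0`` means
    no input.  ``modality`` labels each channel ``"V"`` (a pixel) or
    ``"A"`` (the auditory channel); ``grid_size`` allows mapping pixel
    channels back onto the frame (row-major order).
    """

    symbols: np.ndarray
    modality: tuple
    grid_size: int

    def __post_init__(self):
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.ndim != 2:
            raise ValueError("symbols must be (n_channels, n_steps)")
        if len(self.modality) != self.symbols.shape[0]:
            raise ValueError("one modality label per channel required")

    @property
    def n_channels(self) -> int:
        return self.symbols.shape[0]

    @property
    def n_steps(self) -> int:
        return self.symbols.shape[1]

    def channel(self, idx: int) -> np.ndarray:
        return self.symbols[idx]

    def visual_channels(self) -> np.ndarray:
        return np.array([m == "V" for m in self.modality], dtype=bool)

    def pattern_groups(self, modality: str | None = None) -> dict:
        """Group channel indices by identical input stream.

        Channels whose streams are identical are statistically
        exchangeable copies of the same driven ensemble; the groups are
        both the exact "oracle" clustering of the grid and the basis
        for collapsing a trial into one large ensemble per pattern.
        Keyed by the stream bytes; values are channel-index arrays.
        """
        groups: dict = {}
        for i in range(self.n_channels):
            if modality is not None and self.modality[i] != modality:
                continue
            key = self.symbols[i].tobytes()
            groups.setdefault(key, []).append(i)
        return {k: np.asarray(v) for k, v in groups.items()}

    # --- plain-text round trip -----------------------------------------
    def to_text(self) -> str:
        """One line per channel: whitespace-separated symbols, 0 = blank."""
        return "\n".join(
            " ".join(str(s) for s in row) for row in self.symbols
        )

    @classmethod
    def from_text(cls, text: str, modality=None, grid_size: int = 0) -> "StreamBundle":
        rows = [
            [int(tok) for tok in line.split()]
            for line in text.strip().splitlines()
            if line.strip()
        ]
        sym = np.asarray(rows, dtype=np.int64)
        if modality is None:
            modality = tuple("V" for _ in range(sym.shape[0]))
        return cls(symbols=sym, modality=tuple(modality), grid_size=grid_size)


def make_test_item(sequence, tested_index: int, congruent: bool):
    """The test stimulus probed at 1-based item position ``tested_index``.

    The congruent test item is what the cyclic continuation of the
    sequence would produce at that position; the incongruent one flips
    its label (H/V orientation for unimodal items, H/L level for
    crossmodal items, modality preserved).
    """
    if tested_index < 1:
        raise ValueError("tested_index is 1-based")
    due = sequence.items[(tested_index - 1) % len(sequence)]
    if congruent:
        return due
    if isinstance(sequence, UnimodalSequence):
        return "V" if due == "H" else "H"
    m, l = due
    return (m, "L" if l == "H" else "H")


def _unimodal_frames(size: int) -> dict:
    return {o: render_gabor(o, size=size) for o in UNIMODAL_LABELS}


def _crossmodal_visual_frames(size: int, geometry: str) -> dict:
    return {l: render_disc(l, size=size, geometry=geometry) for l in ("H", "L")}


def build_streams(
    sequence,
    repetitions: int,
    test_item=None,
    *,
    n_items: int | None = None,
    grid_size: int = 20,
    geometry: str = "disjoint",
) -> StreamBundle:
    """Render a repeated sequence (plus optional test item) to streams.

    Each presented item contributes a blank step followed by a stimulus
    step, so the total length is ``2 * n_items`` (+2 with a test item).
    ``n_items`` overrides ``repetitions * len(sequence)`` to stop the
    cyclic presentation mid-sequence (used to probe arbitrary item
    positions).  For unimodal sequences every pixel channel reads the
    black/white value of its own pixel; for crossmodal sequences the
    pixel channels carry ``BRIGHT`` where a disc covers them on visual
    items and ``0`` on auditory items, and one extra auditory channel
    carries the pitch symbol on auditory items and ``0`` elsewhere.
    """
    if repetitions < 1 and n_items is None:
        raise ValueError("repetitions must be >= 1")
    total_items = n_items if n_items is not None else repetitions * len(sequence)
    item_seq = [sequence.items[i % len(sequence)] for i in range(total_items)]
    if test_item is not None:
        item_seq.append(test_item)

    n_pix = grid_size * grid_size
    unimodal = isinstance(sequence, UnimodalSequence)
    if unimodal:
        frames = _unimodal_frames(grid_size)
        for it in item_seq:
            if it not in frames:
                raise ValueError(f"unimodal item {it!r} must be 'H' or 'V'")
        n_channels = n_pix
        modality = tuple("V" for _ in range(n_pix))
    else:
        frames = _crossmodal_visual_frames(grid_size, geometry)
        for it in item_seq:
            if not (isinstance(it, tuple) and len(it) == 2):
                raise ValueError(f"crossmodal item {it!r} must be a (modality, level) pair")
        n_channels = n_pix + 1
        modality = tuple(["V"] * n_pix + ["A"])

    n_steps = 2 * len(item_seq)
    symbols = np.zeros((n_channels, n_steps), dtype=np.int64)
    for k, item in enumerate(item_seq):
        t_stim = 2 * k + 1  # step 2k is the blank slot
        if unimodal:
            symbols[:n_pix, t_stim] = frames[item].ravel()
        else:
            m, l = item
            if m == "V":
                symbols[:n_pix, t_stim] = frames[l].ravel()
            else:
                symbols[n_pix, t_stim] = PITCH_HIGH if l == "H" else PITCH_LOW
    return StreamBundle(symbols=symbols, modality=modality, grid_size=grid_size)


def sequence_entropy(sequence) -> float:
    """Shannon entropy (bits) of the item-label distribution.

    A measure of sequence complexity: 0 for the two constant sequences,
    ``H(1/5) ~ 0.722`` when one item differs from the other four,
    ``H(2/5) ~ 0.971`` for the remaining five-item sequences.
    """
    items = list(sequence.items)
    _, counts = np.unique(np.asarray(items, dtype=object).astype(str), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum()) + 0.0
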