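"""Stimulus and schedule arithmetic for the acuity-sweep alternation paradigm.

Two tasks share a 3 Hz two-state alternation: a Vernier grating whose
alternate bands are periodically displaced and withdrawn, and arrays of
optotype letters alternating with phase-scrambled counterparts. Five
stimulus sizes per task are spaced in equal logMAR steps, spanning
0.15-0.75 logMAR (Vernier offsets, arcmin) and 0.15-1.06 logMAR (letter
heights).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np

__all__ = [
    "ConditionSeries",
    "StimulusFrame",
    "Schedule",
    "arcmin_to_logmar",
    "logmar_to_arcmin",
    "build_series",
    "make_vernier_frames",
    "make_letter_frames",
    "build_schedule",
    "standard_condition_table",
    "VERNIER_LOGMAR_RANGE",
    "LETTER_LOGMAR_RANGE",
]

VERNIER_LOGMAR_RANGE = (0.15, 0.75)
LETTER_LOGMAR_RANGE = (0.15, 1.06)
LOGMAR0_LETTER_ARCMIN = 5.0  # standard optotype height at logMAR 0


class ResolutionError(ValueError):
    """Offset not representable at the requested pixel resolution."""


class LayoutError(ValueError):
    """Stimulus field too small for the requested elements."""


def arcmin_to_logmar(x: float) -> float:
    """logMAR of a visual angle in arcminutes (log10 of the MAR)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("visual angle must be positive")
    return np.log10(x) if x.ndim else float(np.log10(x))


def logmar_to_arcmin(logmar: float) -> float:
    logmar = np.asarray(logmar, dtype=float)
    out = np.power(10.0, logmar)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ConditionSeries:
    """Five (by default) stimulus sizes for one task, ascending in logMAR."""

    task: str
    logmar_levels: tuple[float, ...]
    physical_arcmin: tuple[float, ...]  # Vernier offset or letter height

    def __post_init__(self):
        lv = np.asarray(self.logmar_levels)
        if not np.all(np.diff(lv) > 0):
            raise ValueError("logMAR levels must be strictly increasing")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def build_series(task: str, lo_logmar: float, hi_logmar: float, n: int = 5) -> ConditionSeries:
    """Equally spaced logMAR levels between the endpoints, inclusive.

    Letter heights are anchored to the 5-arcmin optotype at logMAR 0;
    Vernier logMAR converts directly to offset arcminutes.
    """
    if lo_logmar >= hi_logmar:
        raise ValueError("lo_logmar must be < hi_logmar")
    if n < 2:
        raise ValueError("need at least 2 levels")
    if task not in ("vernier", "letter"):
        raise ValueError(f"unknown task {task!r}")
    levels = np.linspace(lo_logmar, hi_logmar, n)
    scale = LOGMAR0_LETTER_ARCMIN if task == "letter" else 1.0
    phys = scale * np.power(10.0, levels)
    return ConditionSeries(task=task, logmar_levels=tuple(np.round(levels, 12)),
                           physical_arcmin=tuple(phys))


@dataclass(frozen=True)
class StimulusFrame:
    """One alternation state as a luminance image in [0, 1]."""

    image: np.ndarray
    pixel_deg: float
    state: str  # "base" or "modulated"

    def __post_init__(self):
        img = self.image
        if img.min() < -1e-12 or img.max() > 1 + 1e-12:
            raise ValueError("luminance must lie in [0, 1]")


# -- Vernier grating -----------------------------------------------------

def _square_wave_columns(n_cols: int, sf_cpd: float, pixel_deg: float,
                         contrast: float) -> np.ndarray:
    x = (np.arange(n_cols) + 0.5) * pixel_deg
    wave = np.sign(np.sin(2 * np.pi * sf_cpd * x))
    wave[wave == 0] = 1.0
    return 0.5 + 0.5 * contrast * wave


def _fractional_roll(row: np.ndarray, shift_px: float) -> np.ndarray:
    """Circular column shift with linear interpolation for fractional parts."""
    k = int(np.floor(shift_px))
    frac = shift_px - k
    rolled = np.roll(row, k)
    if frac == 0:
        return rolled
    return (1 - frac) * rolled + frac * np.roll(row, k + 1)


def make_vernier_frames(offset_arcmin: float, field_deg: float = 12.0,
                        band_height_deg: float = 2.0, sf_cpd: float = 2.0,
                        contrast: float = 0.9, pixel_deg: float = 1 / 60,
                        subpixel: bool = True) -> tuple[StimulusFrame, StimulusFrame]:
    """Base square-wave grating and its Vernier-displaced counterpart.

    The base frame is a vertical square-wave grating (``sf_cpd`` cycles/deg
    horizontally). In the modulated frame, every other horizontal band of
    ``band_height_deg`` is shifted laterally by ``offset_arcmin``; the
    intervening bands are static. Shifts are circular, so the two frames
    have identical mean luminance by construction.
    """
    if offset_arcmin < 0:
        raise ValueError("offset must be >= 0")
    n = int(round(field_deg / pixel_deg))
    row = _square_wave_columns(n, sf_cpd, pixel_deg, contrast)
    base = np.tile(row, (n, 1))

    shift_px = offset_arcmin / 60.0 / pixel_deg
    if 0 < shift_px < 1 and not subpixel:
        raise ResolutionError(
            f"offset {offset_arcmin} arcmin is {shift_px:.2f} px; "
            "enable subpixel rendering or increase resolution")
    if not subpixel:
        shift_px = round(shift_px)
    shifted_row = _fractional_roll(row, shift_px)

    band_px = int(round(band_height_deg / pixel_deg))
    modulated = base.copy()
    for start in range(0, n, 2 * band_px):  # displace alternating bands
        lo = start + band_px
        hi = min(lo + band_px, n)
        if lo < n:
            modulated[lo:hi, :] = shifted_row
    return (StimulusFrame(base, pixel_deg, "base"),
            StimulusFrame(modulated, pixel_deg, "modulated"))


# -- letter arrays -------------------------------------------------------
# The ten Sloan optotype letters drawn as block glyphs on the 5x5 grid that
# Sloan optotypes are designed on; exact glyph outlines are immaterial to
# the analysis, only their size and spatial statistics are.
_GLYPHS = {
    "C": ["11111", "10000", "10000", "10000", "11111"],
    "D": ["11110", "10001", "10001", "10001", "11110"],
    "H": ["10001", "10001", "11111", "10001", "10001"],
    "K": ["10001", "10010", "11100", "10010", "10001"],
    "N": ["10001", "11001", "10101", "10011", "10001"],
    "O": ["11111", "10001", "10001", "10001", "11111"],
    "R": ["11110", "10001", "11110", "10010", "10001"],
    "S": ["11111", "10000", "11111", "00001", "11111"],
    "V": ["10001", "10001", "10001", "01010", "00100"],
    "Z": ["11111", "00010", "00100", "01000", "11111"],
}
SLOAN_LETTERS = tuple(sorted(_GLYPHS))


def _render_glyph(letter: str, size_px: int) -> np.ndarray:
    cells = np.array([[c == "1" for c in row] for row in _GLYPHS[letter]], dtype=float)
    idx = np.minimum((np.arange(size_px) * 5) // size_px, 4)
    return cells[np.ix_(idx, idx)]


def make_letter_frames(letter_height_arcmin: float,
                       field_deg: tuple[float, float] = (9.0, 16.0),
                       pixel_deg: float = 1 / 60,
                       seed: int = 0) -> tuple[StimulusFrame, StimulusFrame]:
    """An intact random-letter array and its phase-scrambled counterpart.

    Letters are laid out with one letter width/height of blank spacing
    between them. Scrambling randomizes Fourier phases while keeping the
    2D amplitude spectrum (hence mean luminance and RMS contrast) identical
    to the intact array; both frames are then mapped jointly into [0, 1]
    by one affine transform, which preserves all of those equalities.
    """
    rng = np.random.default_rng(seed)
    size_px = int(round(letter_height_arcmin / 60.0 / pixel_deg))
    if size_px < 5:
        raise ResolutionError("letter height below 5 pixels cannot be rendered")
    h_px = int(round(field_deg[0] / pixel_deg))
    w_px = int(round(field_deg[1] / pixel_deg))
    pitch = 2 * size_px  # letter + one-letter-width spacing
    n_rows = (h_px + size_px) // pitch
    n_cols = (w_px + size_px) // pitch
    if n_rows < 1 or n_cols < 1:
        raise LayoutError("field too small for a single letter")

    intact = np.zeros((h_px, w_px))
    for r in range(n_rows):
        for c in range(n_cols):
            glyph = _render_glyph(rng.choice(SLOAN_LETTERS), size_px)
            y, x = r * pitch, c * pitch
            intact[y:y + size_px, x:x + size_px] = glyph

    spec = np.fft.fft2(intact)
    rand_phase = np.exp(1j * np.angle(np.fft.fft2(rng.standard_normal(intact.shape))))
    # keep the DC phase so both images share their mean exactly
    rand_phase[0, 0] = 1.0
    scrambled = np.fft.ifft2(np.abs(spec) * rand_phase).real

    lo = min(intact.min(), scrambled.min())
    hi = max(intact.max(), scrambled.max())
    span = hi - lo if hi > lo else 1.0
    intact = (intact - lo) / span
    scrambled = (scrambled - lo) / span
    return (StimulusFrame(intact, pixel_deg, "base"),
            StimulusFrame(scrambled, pixel_deg, "modulated"))


# -- block/trial schedule ------------------------------------------------

@dataclass(frozen=True)
class Schedule:
    """Blocks of (condition_id, trial_duration_s) pairs in presentation order."""

    blocks: tuple[tuple[tuple[int, float], ...], ...]
    seed: int

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.blocks)

    def trials(self):
        """Yield (trial_index, block_index, condition_id, duration_s)."""
        t = 0
        for b, block in enumerate(self.blocks):
            for cond, dur in block:
                yield t, b, cond, dur
                t += 1

    def condition_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for _, _, cond, _ in self.trials():
            counts[cond] = counts.get(cond, 0) + 1
        return counts

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "blocks": [list(map(list, b)) for b in self.blocks]})


def build_schedule(n_blocks: int = 8, per_block_per_cond: int = 2,
                   conditions: int | list[int] = 10, trial_s: float = 12.0,
                   seed: int = 0) -> Schedule:
    """Randomized block design: each block holds ``per_block_per_cond``
    trials of every condition in seeded random order."""
    if isinstance(conditions, int):
        cond_ids = list(range(1, conditions + 1))
    else:
        cond_ids = list(conditions)
    if n_blocks < 1 or per_block_per_cond < 1 or len(cond_ids) < 1:
        raise ValueError("all schedule counts must be >= 1")
    rng = np.random.default_rng(seed)
    blocks = []
    for _ in range(n_blocks):
        pool = np.repeat(cond_ids, per_block_per_cond)
        rng.shuffle(pool)
        blocks.append(tuple((int(c), float(trial_s)) for c in pool))
    return Schedule(blocks=tuple(blocks), seed=seed)


def standard_condition_table():
    """The 10-condition design: ids 1-5 Vernier (0.15-0.75 logMAR),
    ids 6-10 letter (0.15-1.06 logMAR)."""
    import pandas as pd

    rows = []
    vern = build_series("vernier", *VERNIER_LOGMAR_RANGE)
    for i, lv in enumerate(vern.logmar_levels):
        rows.append({"condition": i + 1, "task": "vernier", "logmar": float(lv)})
    lett = build_series("letter", *LETTER_LOGMAR_RANGE)
    for i, lv in enumerate(lett.logmar_levels):
        rows.append({"condition": i + 6, "task": "letter", "logmar": float(lv)})
    return pd.DataFrame(rows)
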