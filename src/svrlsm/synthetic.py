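"""Synthetic lesion-behavior cohorts with known ground truth.

The generator emulates the statistical structure a lesion-symptom
mapping of verbal working memory assumes, at desk scale:

* clustered, volume-heterogeneous lesions confined to one hemisphere
  (unions of smoothed random blobs around a vascular-territory-like
  center of mass);
* two disjoint planted critical regions — region A drives a digit-span
  (phonological WM) deficit in proportion to its lesioned fraction,
  region B drives word-length sensitivity in spelling (orthographic
  WM); an optional third region C drives word-frequency sensitivity
  (orthographic LTM), so the selective-vs-dual deficit taxonomy arises
  naturally;
* covariate effects (age, gender) and Gaussian noise on the latent
  scores;
* trial-level realism: digit-span administrations that obey the
  two-lists-per-length stopping rule, and letter-level spelling errors
  (substitutions, deletions, adjacent transpositions) on a balanced
  pseudo-word list straddling the frequency and length bins.

Everything is reproducible from (config, seed). The default grid is
2 mm and small so a full permutation analysis runs in minutes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .behavioral import DigitSpanRecord, SpellingTrial, digit_span
from .exceptions import ConfigError
from .inference import ThresholdResult
from .lesions import LesionMask, LesionMatrix, lesion_volume_cc

__all__ = [
    "RegionSpec",
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_lesions",
    "generate_behavior",
    "generate_cohort",
    "make_word_list",
    "load_word_list",
    "realize_digit_span",
    "dice_coefficient",
    "recovery_metrics",
]

_WORD_LIST_SEED = 7  # fixed: the packaged word list is itself a fixture


@dataclass(frozen=True)
class RegionSpec:
    """A spherical critical region: center in voxel coordinates, radius in mm."""

    center: tuple[int, int, int]
    radius_mm: float

    def grid(self, shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
        if self.radius_mm <= 0:
            raise ConfigError("region radius must be positive")
        ii, jj, kk = np.ogrid[: shape[0], : shape[1], : shape[2]]
        d2 = (
            (ii - self.center[0]) ** 2
            + (jj - self.center[1]) ** 2
            + (kk - self.center[2]) ** 2
        ) * voxel_size**2
        out = d2 <= self.radius_mm**2
        if not out.any():
            raise ConfigError(f"region at {self.center} lies outside the grid")
        edge = (
            min(self.center) < 0
            or any(c >= s for c, s in zip(self.center, shape))
        )
        if edge:
            raise ConfigError(f"region center {self.center} outside grid {shape}")
        return out


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror a 37-participant chronic left-hemisphere stroke
    cohort on a 40x48x40 grid of 2 mm voxels. Effect sizes are on the
    scale of the behavioral variables: ``span_loss`` is the digit-span
    cost of completely lesioning region A (severe phonological WM
    deficits reach spans of 0-2.5 from a baseline near 7);
    ``length_slope`` and ``freq_slope`` are the added per-letter error
    probability, for long or low-frequency words respectively, when the
    corresponding region is fully lesioned.
    """

    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 2.0
    n_participants: int = 37
    seed: int = 0

    # lesion model: blobs drawn around one of two vascular-territory-like
    # centers of mass, confined to the x < grid_shape[0] // 2 half
    # ("left hemisphere"); big-radius draws spill across territories
    max_blobs: int = 3
    territory_mus: tuple[tuple[float, float, float], ...] = (
        (11.0, 30.0, 20.0),  # posterior division (covers regions A and C)
        (11.0, 19.0, 22.0),  # anterior division (covers region B)
    )
    territory_sds: tuple[tuple[float, float, float], ...] = (
        (3.0, 5.0, 4.0),
        (3.0, 5.0, 4.0),
    )
    territory_probs: tuple[float, ...] = (0.55, 0.45)
    blob_radius_log_mean_mm: float = 2.4  # exp(2.4) ~ 11 mm
    blob_radius_log_sd: float = 0.35
    blob_radius_clip_mm: tuple[float, float] = (6.0, 30.0)
    smooth_mm: float = 4.0
    smooth_threshold: float = 0.4

    # planted critical regions (disjoint; all in the left half-grid)
    region_a: RegionSpec = field(default_factory=lambda: RegionSpec((11, 31, 21), 8.0))
    region_b: RegionSpec = field(default_factory=lambda: RegionSpec((11, 19, 23), 8.0))
    region_c: RegionSpec = field(default_factory=lambda: RegionSpec((13, 36, 15), 8.0))

    # behavioral model
    span_baseline: float = 7.0
    span_loss: float = 6.0
    span_noise_sd: float = 0.5
    age_coef: float = -0.03  # span points per year above 60
    gender_coef: float = -0.2
    base_letter_error: float = 0.03
    length_slope: float = 0.35
    freq_slope: float = 0.35
    max_letter_error: float = 0.85
    error_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)  # sub, del, transpose
    n_words: int = 80

    # covariate distributions
    age_mean: float = 62.0
    age_sd: float = 10.0
    ppvt_mean: float = 60.0
    ppvt_sd: float = 25.0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("need at least two participants")
        if min(self.blob_radius_clip_mm) <= 0:
            raise ConfigError("blob radii must be positive")
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise ConfigError("error_mix must sum to 1")
        if len(self.territory_mus) != len(self.territory_sds) or len(
            self.territory_mus
        ) != len(self.territory_probs):
            raise ConfigError("territory mus, sds and probs must align")
        if abs(sum(self.territory_probs) - 1.0) > 1e-9:
            raise ConfigError("territory_probs must sum to 1")
        a = self.region_a.grid(self.grid_shape, self.voxel_size_mm)
        b = self.region_b.grid(self.grid_shape, self.voxel_size_mm)
        c = self.region_c.grid(self.grid_shape, self.voxel_size_mm)
        if (a & b).any() or (a & c).any() or (b & c).any():
            raise ConfigError("critical regions must be pairwise disjoint")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -np.asarray(self.grid_shape) * self.voxel_size_mm / 2.0
        return aff


@dataclass
class SyntheticCohort:
    """A generated cohort: masks, ground truth, behavior, and provenance."""

    masks: list[LesionMask]
    truth: dict[str, np.ndarray]  # region name -> binary grid
    behavior: pd.DataFrame
    digit_records: dict[str, DigitSpanRecord]
    spelling_trials: dict[str, list[SpellingTrial]]
    loads: pd.DataFrame  # lesioned fraction of each region, per participant
    config: SyntheticConfig

    @property
    def participant_ids(self) -> list[str]:
        return [m.participant_id for m in self.masks]


# ---------------------------------------------------------------------------
# Lesions
# ---------------------------------------------------------------------------

def generate_lesions(config: SyntheticConfig, rng: np.random.Generator | None = None
                     ) -> list[LesionMask]:
    """Draw one clustered binary lesion per participant.

    Each lesion is a union of spherical blobs with lognormal radii,
    Gaussian-smoothed and re-thresholded for irregular borders, then
    clipped to the left half-grid. Radius and blob-count variation
    yields volumes spanning well over a five-fold range.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    shape = config.grid_shape
    half = shape[0] // 2
    ii, jj, kk = np.ogrid[: shape[0], : shape[1], : shape[2]]
    masks = []
    for p in range(config.n_participants):
        pid = f"sub-{p + 1:03d}"
        for _attempt in range(20):
            n_blobs = int(rng.integers(1, config.max_blobs + 1))
            territory = int(rng.choice(len(config.territory_probs), p=config.territory_probs))
            union = np.zeros(shape, dtype=float)
            for _ in range(n_blobs):
                center = rng.normal(config.territory_mus[territory],
                                    config.territory_sds[territory])
                center = np.clip(center, 2, np.asarray(shape) - 3)
                radius = float(np.clip(
                    rng.lognormal(config.blob_radius_log_mean_mm, config.blob_radius_log_sd),
                    *config.blob_radius_clip_mm,
                ))
                d2 = (
                    (ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2
                ) * config.voxel_size_mm**2
                union[d2 <= radius**2] = 1.0
            smoothed = gaussian_filter(union, config.smooth_mm / config.voxel_size_mm)
            grid = (smoothed > config.smooth_threshold)
            grid[half:] = False
            if grid.any():
                break
        else:
            raise ConfigError(
                "lesion model produced empty masks; check blob radii and smoothing"
            )
        masks.append(LesionMask(pid, grid.astype(np.uint8), config.affine))
    return masks


def region_load(mask: LesionMask, region: np.ndarray) -> float:
    """Fraction of a region's voxels covered by the lesion."""
    return float(mask.grid[region.astype(bool)].mean())


# ---------------------------------------------------------------------------
# Word list fixture
# ---------------------------------------------------------------------------

_CONSONANTS = "BCDFGKLMNPRSTV"
_VOWELS = "AEIOU"


def make_word_list(n_words: int = 80, seed: int = _WORD_LIST_SEED) -> pd.DataFrame:
    """Synthesize a balanced pseudo-word spelling list.

    Equal numbers of 4-, 5-, 7- and 8-letter pronounceable pseudo-words
    (alternating consonant-vowel frames), half assigned low printed
    frequencies (< 15 per million) and half high (> 60 per million), so
    the length bins (4-5 vs 7-8 letters) and frequency bins are fully
    crossed. Deterministic for a given seed; the packaged CSV is the
    output at the default seed.
    """
    if n_words % 8:
        raise ConfigError("n_words must be divisible by 8 (4 lengths x 2 freq bins)")
    rng = np.random.default_rng(seed)
    per_cell = n_words // 8
    rows = []
    seen = set()
    for length in (4, 5, 7, 8):
        for low_freq in (True, False):
            for _ in range(per_cell):
                while True:
                    chars = []
                    for pos in range(length):
                        pool = _CONSONANTS if pos % 2 == 0 else _VOWELS
                        chars.append(pool[rng.integers(len(pool))])
                    word = "".join(chars)
                    if word not in seen:
                        seen.add(word)
                        break
                freq = rng.uniform(1.0, 10.0) if low_freq else rng.uniform(80.0, 300.0)
                rows.append((word, length, round(float(freq), 1)))
    return pd.DataFrame(rows, columns=["word", "length", "frequency_per_million"])


def load_word_list() -> pd.DataFrame:
    """Load the packaged 80-item synthetic spelling list."""
    ref = importlib.resources.files("svrlsm.data").joinpath("word_list.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def realize_digit_span(span: float) -> DigitSpanRecord:
    """Construct a digit-span administration scoring exactly ``span``.

    The span is clipped to [0, 9] and quantized to half points. Spans
    of two or more are realized as perfect performance through the base
    length, one correct list at the next length when a half point is
    needed, then failure; sub-span scores are realized as a run of
    single-correct lengths (each worth half a point) before failure.
    """
    span = float(np.clip(round(span * 2) / 2, 0.0, 9.0))
    trials: dict[int, tuple[int, int]] = {}
    if span >= 2:
        base = int(span)
        for length in range(2, base + 1):
            trials[length] = (2, 2)
        nxt = base + 1
        if span > base and nxt <= 9:
            trials[nxt] = (2, 1)
            nxt += 1
        if nxt <= 9:
            trials[nxt] = (2, 0)
    else:
        halves = int(round(span / 0.5))
        length = 2
        for _ in range(halves):
            trials[length] = (2, 1)
            length += 1
        trials[length] = (2, 0)
    return DigitSpanRecord(trials)


def _corrupt_word(word: str, p_error: float, mix: tuple[float, float, float],
                  rng: np.random.Generator) -> str:
    """Apply letter-level errors: substitutions, deletions, transpositions."""
    letters = list(word)
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    i = 0
    out = []
    while i < len(letters):
        if rng.random() >= p_error:
            out.append(letters[i])
            i += 1
            continue
        op = rng.choice(3, p=mix)
        if op == 0:  # substitution
            repl = alphabet[rng.integers(26)]
            while repl == letters[i]:
                repl = alphabet[rng.integers(26)]
            out.append(repl)
            i += 1
        elif op == 1:  # deletion
            i += 1
        else:  # adjacent transposition (falls back to substitution at word end)
            if i + 1 < len(letters):
                out.append(letters[i + 1])
                out.append(letters[i])
                i += 2
            else:
                repl = alphabet[rng.integers(26)]
                while repl == letters[i]:
                    repl = alphabet[rng.integers(26)]
                out.append(repl)
                i += 1
    return "".join(out)


def simulate_spelling_trials(
    load_b: float,
    load_c: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    words: pd.DataFrame | None = None,
) -> list[SpellingTrial]:
    """Spell the word list once with region-load-dependent letter errors.

    The per-letter error probability is the base rate plus
    ``length_slope * load_b`` for long (7-8 letter) words and
    ``freq_slope * load_c`` for low-frequency (< 15 per million) words,
    the planted signatures of orthographic WM and orthographic LTM
    damage respectively.
    """
    words = load_word_list() if words is None else words
    trials = []
    for row in words.itertuples(index=False):
        p = config.base_letter_error
        if row.length >= 7:
            p += config.length_slope * load_b
        if row.frequency_per_million < 15:
            p += config.freq_slope * load_c
        p = min(p, config.max_letter_error)
        response = _corrupt_word(row.word, p, config.error_mix, rng)
        trials.append(SpellingTrial(row.word, response, row.frequency_per_million))
    return trials


def generate_behavior(
    masks: Sequence[LesionMask],
    truth: dict[str, np.ndarray],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, DigitSpanRecord], dict[str, list[SpellingTrial]], pd.DataFrame]:
    """Generate covariates, digit-span records and spelling trials.

    Digit span follows ``baseline - span_loss * load_A`` plus age and
    gender terms and Gaussian noise, discretized through a
    stopping-rule-consistent administration. Spelling follows the
    letter-error model above. Returns (behavior table, digit records,
    spelling trials, region loads).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    words = load_word_list()
    rows, load_rows = [], []
    digit_records: dict[str, DigitSpanRecord] = {}
    spelling: dict[str, list[SpellingTrial]] = {}
    for mask in masks:
        pid = mask.participant_id
        load_a = region_load(mask, truth["A"])
        load_b = region_load(mask, truth["B"])
        load_c = region_load(mask, truth["C"])
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 25, 90))
        gender = int(rng.integers(2))
        ppvt = float(np.clip(rng.normal(config.ppvt_mean, config.ppvt_sd), 1, 99))
        noise = rng.normal(0.0, config.span_noise_sd) if config.span_noise_sd > 0 else 0.0
        latent_span = (
            config.span_baseline
            - config.span_loss * load_a
            + config.age_coef * (age - config.age_mean)
            + config.gender_coef * gender
            + noise
        )
        record = realize_digit_span(latent_span)
        span = digit_span(record)
        digit_records[pid] = record
        spelling[pid] = simulate_spelling_trials(load_b, load_c, config, rng, words)
        rows.append({
            "participant_id": pid,
            "age": age,
            "gender": gender,
            "ppvt_percentile": ppvt,
            "digit_span": span,
            "lesion_volume_cc": lesion_volume_cc(mask),
        })
        load_rows.append({
            "participant_id": pid,
            "load_A": load_a,
            "load_B": load_b,
            "load_C": load_c,
        })
    return (
        pd.DataFrame(rows),
        digit_records,
        spelling,
        pd.DataFrame(load_rows),
    )


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate a complete cohort from one config (and its seed)."""
    config = SyntheticConfig() if config is None else config
    config.validate()
    rng = np.random.default_rng(config.seed)
    masks = generate_lesions(config, rng)
    truth = {
        "A": config.region_a.grid(config.grid_shape, config.voxel_size_mm).astype(np.uint8),
        "B": config.region_b.grid(config.grid_shape, config.voxel_size_mm).astype(np.uint8),
        "C": config.region_c.grid(config.grid_shape, config.voxel_size_mm).astype(np.uint8),
    }
    behavior, digit_records, spelling, loads = generate_behavior(masks, truth, config, rng)
    return SyntheticCohort(masks, truth, behavior, digit_records, spelling, loads, config)


# ---------------------------------------------------------------------------
# Recovery instrumentation
# ---------------------------------------------------------------------------

def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 0 when both sets are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a & b).sum() / denom)


def recovery_metrics(
    truth: dict[str, np.ndarray],
    results: dict[str, ThresholdResult],
    matrix: LesionMatrix,
    own: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Dice of each analysis's significant set against each true region.

    ``own`` names the region each analysis is supposed to recover
    (default: PWM -> A, OWM -> B); overlap with any other region is
    leakage. Significant sets are scattered back onto the grid before
    comparison, so the metric is volumetric.
    """
    own = {"pwm": "A", "owm": "B"} if own is None else own
    rows = []
    for analysis, result in results.items():
        sig = matrix.to_volume(result.significant.astype(float)) > 0.5
        for region, grid in truth.items():
            rows.append({
                "analysis": analysis,
                "region": region,
                "dice": dice_coefficient(sig, grid),
                "relation": "own" if own.get(analysis) == region else "other",
                "n_significant": int(sig.sum()),
            })
    return pd.DataFrame(rows)
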