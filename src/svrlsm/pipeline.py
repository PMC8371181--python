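"""End-to-end orchestration of the two lesion-symptom analyses.

The phonological working memory (PWM) analysis regresses digit span on
the lesion matrix, covarying picture-vocabulary percentile (a
phonological long-term memory control), age, gender and lesion volume.
The orthographic working memory (OWM) analysis uses the categorical
selective-OWM variable (-1 / +1 demeaned, dual deficits 0) with age,
gender and lesion volume covariates. Each analysis: residualize ->
orient -> fit SVR -> beta map -> permutation null -> thresholds at the
four null ranks -> clusters; when both run, an overlap report compares
their significant sets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .behavioral import (
    classify_deficits,
    construct_owm_variable,
    digit_span,
    read_digit_span_records,
    read_spelling_trials,
)
from .estimator import SVRLSM, residualize, residualize_matrix
from .exceptions import ConfigError, InvalidCohortError
from .inference import (
    DEFAULT_RANKS,
    build_null,
    extract_clusters,
    overlap_report,
    threshold_map,
)
from .lesions import (
    LesionMask,
    build_lesion_matrix,
    overlap_map,
    read_mask,
    write_overlap_map,
)
from .synthetic import SyntheticCohort, SyntheticConfig, generate_cohort

log = logging.getLogger("svrlsm")

__all__ = ["AnalysisSpec", "RunConfig", "run_analysis", "load_cohort_dir", "write_cohort_dir"]


@dataclass
class AnalysisSpec:
    """One SVR-LSM analysis: dependent variable, covariates, orientation.

    ``orient = -1`` means lower scores indicate a worse deficit (digit
    span; the OWM code, where selective OWM is the negative pole), so
    the score is negated before fitting to make larger beta = stronger
    lesion-deficit association.
    """

    name: str
    dependent: str
    covariates: list[str]
    orient: int = -1


DEFAULT_ANALYSES = {
    "pwm": AnalysisSpec(
        "pwm", "digit_span",
        ["ppvt_percentile", "age", "gender", "lesion_volume_cc"],
    ),
    "owm": AnalysisSpec(
        "owm", "owm_code",
        ["age", "gender", "lesion_volume_cc"],
    ),
}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: cohort, model, inference, seed."""

    cohort_dir: str | None = None
    synthetic: SyntheticConfig | None = None
    analyses: dict[str, AnalysisSpec] = field(
        default_factory=lambda: {k: dataclasses.replace(v) for k, v in DEFAULT_ANALYSES.items()}
    )
    kernel: str = "rbf"
    C: float = 30.0
    gamma: float = 5.0
    epsilon: float = 0.1
    dtlvc: bool = False
    lesion_covariates: bool = False  # also regress covariates out of voxel columns
    permute_raw: bool = False  # permute raw scores and re-residualize per permutation
    min_overlap: int = 4
    n_perm: int = 5000
    alpha: float = 0.05
    ranks: tuple[int, ...] = DEFAULT_RANKS
    connectivity: int = 26
    tail: str = "deficit"
    seed: int = 0
    output_dir: str = "svrlsm-output"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "synthetic" in raw:
            kwargs["synthetic"] = SyntheticConfig(**raw.pop("synthetic"))
        if "analyses" in raw:
            kwargs["analyses"] = {
                name: AnalysisSpec(name=name, **spec)
                for name, spec in raw.pop("analyses").items()
            }
        if "ranks" in raw:
            raw["ranks"] = tuple(raw["ranks"])
        kwargs.update(raw)
        return cls(**kwargs)

    def model(self) -> SVRLSM:
        return SVRLSM(kernel=self.kernel, C=self.C, gamma=self.gamma,
                      epsilon=self.epsilon, dtlvc=self.dtlvc)


def derive_seed(seed: int, label: str) -> int:
    """Stable per-analysis sub-seed below 2**31."""
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) % 1000003
    return (seed * 1000003 + h) % (2**31)


# ---------------------------------------------------------------------------
# Cohort loading / writing
# ---------------------------------------------------------------------------

def write_cohort_dir(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a synthetic cohort as an on-disk dataset (NIfTI + CSV + JSON)."""
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for mask in cohort.masks:
        nib.Nifti1Image(mask.grid, mask.affine).to_filename(
            str(out / "masks" / f"{mask.participant_id}.nii.gz")
        )
    for name, grid in cohort.truth.items():
        nib.Nifti1Image(np.asarray(grid, dtype=np.uint8), cohort.config.affine).to_filename(
            str(out / "truth" / f"region_{name}.nii.gz")
        )
    write_overlap_map(overlap_map(cohort.masks), out / "overlap_map.nii.gz")
    cohort.behavior.to_csv(out / "behavior.csv", index=False)
    cohort.loads.to_csv(out / "region_loads.csv", index=False)
    digit_rows = [
        {"participant_id": pid, "list_length": length,
         "administered": adm, "correct": cor}
        for pid, rec in cohort.digit_records.items()
        for length, (adm, cor) in sorted(rec.trials.items())
    ]
    pd.DataFrame(digit_rows).to_csv(out / "digit_span.csv", index=False)
    trial_rows = [
        {"participant_id": pid, "target": t.target, "response": t.response,
         "frequency_per_million": t.frequency_per_million}
        for pid, trials in cohort.spelling_trials.items()
        for t in trials
    ]
    pd.DataFrame(trial_rows).to_csv(out / "spelling.csv", index=False)
    cfg = dataclasses.asdict(cohort.config)
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=list)
    return out


@dataclass
class Cohort:
    """A cohort ready for analysis, whatever its origin."""

    masks: list[LesionMask]
    behavior: pd.DataFrame  # indexed by participant_id column
    spelling_trials: dict
    ppe_flags: dict[str, bool]


def load_cohort_dir(path) -> Cohort:
    """Load a cohort directory (as written by ``write_cohort_dir`` or
    assembled by hand): masks/*.nii.gz, behavior.csv, digit_span.csv,
    spelling.csv, optional ppe.csv (participant_id, ppe_present)."""
    path = Path(path)
    mask_files = sorted((path / "masks").glob("*.nii*"))
    if not mask_files:
        raise ConfigError(f"no lesion masks under {path / 'masks'}")
    masks = [read_mask(f) for f in mask_files]
    behavior = pd.read_csv(path / "behavior.csv")
    if (path / "digit_span.csv").exists() and "digit_span" not in behavior:
        records = read_digit_span_records(path / "digit_span.csv")
        behavior["digit_span"] = [
            digit_span(records[pid]) for pid in behavior["participant_id"]
        ]
    spelling = {}
    if (path / "spelling.csv").exists():
        spelling = read_spelling_trials(path / "spelling.csv")
    ppe = {}
    if (path / "ppe.csv").exists():
        ppe_df = pd.read_csv(path / "ppe.csv")
        ppe = dict(zip(ppe_df["participant_id"].astype(str),
                       ppe_df["ppe_present"].astype(bool)))
    return Cohort(masks, behavior, spelling, ppe)


def _as_cohort(obj) -> Cohort:
    if isinstance(obj, Cohort):
        return obj
    if isinstance(obj, SyntheticCohort):
        return Cohort(obj.masks, obj.behavior.copy(), obj.spelling_trials, {})
    raise ConfigError(f"cannot interpret {type(obj).__name__} as a cohort")


def prepare_behavior(cohort: Cohort, alpha: float = 0.05) -> pd.DataFrame:
    """Score spelling, type deficits, and attach the OWM code.

    Participants with no spelling deficit get no ``owm_code`` (NaN) and
    are excluded from the OWM analysis downstream; their ids are logged.
    """
    table = cohort.behavior.copy()
    table["participant_id"] = table["participant_id"].astype(str)
    if cohort.spelling_trials:
        profiles = []
        for pid in table["participant_id"]:
            trials = cohort.spelling_trials.get(pid)
            if not trials:
                continue
            profiles.append(classify_deficits(
                trials, cohort.ppe_flags.get(pid, False),
                alpha=alpha, participant_id=pid,
            ))
        typed = {p.participant_id: p.deficit_type for p in profiles}
        table["deficit_type"] = table["participant_id"].map(typed)
        with_deficit = {
            pid: dtype for pid, dtype in typed.items() if dtype != "none"
        }
        dropped = sorted(set(typed) - set(with_deficit))
        if dropped:
            log.info("no spelling deficit, excluded from OWM analysis: %s",
                     ", ".join(dropped))
        if with_deficit and any(v in ("OWM", "OLTM") for v in with_deficit.values()):
            codes = construct_owm_variable(with_deficit)
            table["owm_code"] = table["participant_id"].map(codes)
        else:
            table["owm_code"] = np.nan
    return table


# ---------------------------------------------------------------------------
# The analyses
# ---------------------------------------------------------------------------

def _run_one(spec: AnalysisSpec, cohort: Cohort, table: pd.DataFrame,
             config: RunConfig) -> dict:
    if spec.dependent not in table.columns:
        raise InvalidCohortError(
            f"{spec.name}: dependent variable {spec.dependent!r} not in behavioral table"
        )
    missing = [c for c in spec.covariates if c not in table.columns]
    if missing:
        raise InvalidCohortError(f"{spec.name}: missing covariates {missing}")
    usable = table.dropna(subset=[spec.dependent] + spec.covariates)
    dropped = sorted(set(table["participant_id"]) - set(usable["participant_id"]))
    if dropped:
        log.info("%s: dropping participants without complete data: %s",
                 spec.name, ", ".join(map(str, dropped)))
    if spec.dependent == "owm_code" and "deficit_type" in usable.columns:
        bad = usable[usable["deficit_type"] == "none"]
        if len(bad):
            raise InvalidCohortError(
                f"OWM analysis includes participants with no spelling deficit: "
                f"{sorted(bad['participant_id'])}"
            )
    keep_ids = list(usable["participant_id"])
    mask_by_id = {m.participant_id: m for m in cohort.masks}
    missing_masks = [pid for pid in keep_ids if pid not in mask_by_id]
    if missing_masks:
        raise InvalidCohortError(f"{spec.name}: no lesion mask for {missing_masks}")
    masks = [mask_by_id[pid] for pid in keep_ids]
    log.info("%s: %d participants", spec.name, len(masks))

    matrix = build_lesion_matrix(masks, min_overlap=config.min_overlap)
    log.info("%s: %d voxels lesioned in >= %d participants",
             spec.name, matrix.n_voxels, config.min_overlap)
    y = usable[spec.dependent].to_numpy(dtype=float)
    Z = usable[spec.covariates].to_numpy(dtype=float)
    y_resid = residualize(y, Z)
    y_oriented = spec.orient * y_resid
    X_fit = matrix.X
    if config.lesion_covariates:
        X_fit = residualize_matrix(X_fit, Z)

    model = config.model()
    model.fit(X_fit, y_oriented)
    null = build_null(
        X_fit, y_oriented, model,
        n_perm=config.n_perm,
        seed=derive_seed(config.seed, spec.name),
        ranks=config.ranks,
        tail=config.tail,
        raw=(spec.orient * y, Z) if config.permute_raw else None,
    )
    beta = np.abs(model.beta_) if config.tail == "two-sided" else model.beta_
    thresholds = {
        rank: threshold_map(model.beta_, null, rank=rank, alpha=config.alpha)
        for rank in null.ranks
    }
    clusters = extract_clusters(
        thresholds[null.ranks[0]], model.beta_, matrix,
        connectivity=config.connectivity,
    )
    log.info("%s: %d significant voxels at strictest rank, %d clusters",
             spec.name, thresholds[null.ranks[0]].n_significant, len(clusters))
    return {
        "spec": spec,
        "participant_ids": keep_ids,
        "matrix": matrix,
        "model": model,
        "beta": model.beta_,
        "null": null,
        "thresholds": thresholds,
        "clusters": clusters,
    }


def _write_analysis(res: dict, out: Path, config: RunConfig) -> None:
    name = res["spec"].name
    matrix = res["matrix"]
    affine = matrix.affine
    nib.Nifti1Image(
        matrix.to_volume(res["beta"], fill=np.nan).astype(np.float32), affine
    ).to_filename(str(out / f"beta_{name}.nii.gz"))
    for rank, thr in res["thresholds"].items():
        vol = matrix.to_volume(thr.significant.astype(float)).astype(np.uint8)
        nib.Nifti1Image(vol, affine).to_filename(
            str(out / f"significant_{name}_rank{rank}.nii.gz")
        )
    res["null"].save(out / f"null_{name}.npz")
    rows = [
        {
            "id": c.id,
            "voxel_count": c.voxel_count,
            "volume_mm3": c.volume_mm3,
            "centroid_x": round(c.centroid_world_mm[0], 2),
            "centroid_y": round(c.centroid_world_mm[1], 2),
            "centroid_z": round(c.centroid_world_mm[2], 2),
            "peak_beta": c.peak_beta,
            "label": c.atlas_label or "",
        }
        for c in res["clusters"]
    ]
    pd.DataFrame(
        rows, columns=["id", "voxel_count", "volume_mm3", "centroid_x",
                       "centroid_y", "centroid_z", "peak_beta", "label"]
    ).to_csv(out / f"clusters_{name}.csv", index=False)


def run_analysis(config: RunConfig, which: str = "both", cohort=None) -> dict:
    """Run the configured analyses and write all artifacts.

    ``which`` selects 'pwm', 'owm' or 'both'. A cohort object can be
    passed directly; otherwise it is loaded from ``config.cohort_dir``
    or generated from ``config.synthetic``. Returns the in-memory
    results keyed by analysis name (plus 'overlap' when both ran).
    """
    if which not in ("pwm", "owm", "both"):
        raise ConfigError(f"which must be 'pwm', 'owm' or 'both', got {which!r}")
    if cohort is None:
        if config.cohort_dir:
            cohort = load_cohort_dir(config.cohort_dir)
        elif config.synthetic is not None:
            cohort = generate_cohort(config.synthetic)
        else:
            raise ConfigError("config names neither a cohort directory nor a synthetic cohort")
    cohort = _as_cohort(cohort)
    table = prepare_behavior(cohort, alpha=config.alpha)

    names = ["pwm", "owm"] if which == "both" else [which]
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    for name in names:
        if name not in config.analyses:
            raise ConfigError(f"no analysis block named {name!r} in config")
        results[name] = _run_one(config.analyses[name], cohort, table, config)
        _write_analysis(results[name], out, config)
    if len(names) == 2:
        strict = config.ranks[0]
        a, b = results["pwm"], results["owm"]
        if a["matrix"].n_voxels == b["matrix"].n_voxels and np.array_equal(
            a["matrix"].voxel_index, b["matrix"].voxel_index
        ):
            report = {
                str(rank): overlap_report(a["thresholds"][rank], b["thresholds"][rank])
                for rank in config.ranks
            }
        else:
            # participant sets differ, so compare volumetrically
            report = {}
            for rank in config.ranks:
                va = a["matrix"].to_volume(
                    a["thresholds"][rank].significant.astype(float)) > 0.5
                vb = b["matrix"].to_volume(
                    b["thresholds"][rank].significant.astype(float)) > 0.5
                report[str(rank)] = {
                    "a_only": int((va & ~vb).sum()),
                    "b_only": int((vb & ~va).sum()),
                    "both": int((va & vb).sum()),
                    "a_total": int(va.sum()),
                    "b_total": int(vb.sum()),
                }
        results["overlap"] = report
        with open(out / "overlap_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    provenance = {
        "package_version": _pkg_version,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("analyses", "synthetic")
        },
        "analyses": {
            name: dataclasses.asdict(config.analyses[name]) for name in names
        },
        "synthetic": dataclasses.asdict(config.synthetic) if config.synthetic else None,
        "participants": {name: results[name]["participant_ids"] for name in names},
        "conventions": {
            "tail": config.tail,
            "beta": "dual-coefficient back-projection",
            "covariate_control": "behavioral residualization before fitting",
            "permutation_unit": "residualized scores",
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=list)
    return results
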