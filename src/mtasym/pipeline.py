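"""End-to-end orchestration: cohort -> groom -> shape model -> asymmetry ->
matching -> point-wise statistics -> report.

Every run writes a manifest (config, seed, package version), the stage
outputs defined by the individual modules, and a QC log of rejected shapes
with reasons.  A saved config re-runs to identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymmetry import AsymmetryTable, build_asymmetry_table
from .grooming import (DEFAULT_BLUR_SIGMA, DEFAULT_ISO_SPACING,
                       DEFAULT_ITERATIONS, groom)
from .io import save_asymmetry, save_mask, save_shape_model, write_vtk_polydata
from .matching import MatchResult, match_controls
from .shape_model import build_shape_model, flip_sagittal
from .stats import (ALPHA, build_design, default_comparisons,
                    hc_baseline_comparison, run_family, significance_map,
                    volume_group_test)
from .synthetic import CohortConfig, generate_cohort
from .types import DEFAULT_N_POINTS, PipelineError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Fully serializable run configuration."""

    input_mode: str = "synthetic"              # synthetic | nifti_dir
    input_dir: str | None = None               # for nifti_dir mode
    structures: tuple[str, ...] = ("hippocampus", "amygdala")
    n_points: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_POINTS))
    iso_spacing: float = DEFAULT_ISO_SPACING
    smoothing_iterations: int = DEFAULT_ITERATIONS
    blur_sigma: float = DEFAULT_BLUR_SIGMA
    match_ratio: int = 5
    alpha: float = ALPHA
    sensitivity_mode: bool = False
    run_matching: bool = False
    pooled_fdr: bool = True
    seed: int = 0
    output_dir: str = "mtasym_out"
    cohort: CohortConfig | None = None
    save_masks: bool = False

    def to_dict(self) -> dict:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple, set, frozenset)):
                seq = sorted(x) if isinstance(x, (set, frozenset)) else x
                return [plain(v) for v in seq]
            return x

        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = dataclasses.asdict(self.cohort)
            d["cohort"]["effects"] = [dataclasses.asdict(e)
                                      for e in self.cohort.effects]
        return plain(d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             default_flow_style=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .synthetic import EffectSpec
        d = dict(d)
        coh = d.pop("cohort", None)
        cfg = cls(**{k: v for k, v in d.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        if coh is not None:
            effects = tuple(
                EffectSpec(**{**e, "affected_groups":
                              frozenset(e["affected_groups"])})
                for e in coh.pop("effects", []))
            for key in ("n_per_group",):
                if key in coh:
                    coh[key] = dict(coh[key])
            for key in ("voxel_spacing", "structures", "hippocampus_axes",
                        "amygdala_axes"):
                if key in coh:
                    coh[key] = tuple(coh[key])
            cfg.cohort = CohortConfig(**coh, effects=effects)
        return cfg


def _load_nifti_cohort(input_dir: str):
    """Read a directory of masks plus covariates.csv.

    Expected layout: ``<pid>_<side>_<structure>.nii[.gz]`` and a
    ``covariates.csv`` indexed by participant_id.
    """
    from .io import load_mask
    root = Path(input_dir)
    cov_path = root / "covariates.csv"
    if not cov_path.exists():
        raise PipelineError(f"{cov_path} not found")
    covariates = pd.read_csv(cov_path, index_col="participant_id")
    masks = {}
    for p in sorted(root.glob("*.nii*")):
        stem = p.name.split(".nii")[0]
        try:
            pid, side, structure = stem.rsplit("_", 2)
        except ValueError:
            raise PipelineError(f"cannot parse mask filename {p.name}")
        masks[(pid, side, structure)] = load_mask(p)
    if not masks:
        raise PipelineError(f"no NIfTI masks found in {root}")
    return covariates, masks


def _stage(name):
    def wrap(fn):
        def inner(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e
            log.info("stage %-12s %.2f s", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


@dataclass
class PipelineResult:
    covariates: pd.DataFrame
    asymmetry: dict[str, AsymmetryTable]
    pointwise: dict[str, pd.DataFrame]
    volume_tests: dict[str, pd.DataFrame]
    hc_baseline: dict[str, pd.DataFrame]
    matching: dict[str, MatchResult]
    models: dict
    qc: pd.DataFrame
    output_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.yaml")

    if config.input_mode == "synthetic":
        cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
        covariates, masks = _stage("simulate")(generate_cohort)(cohort_cfg)
    elif config.input_mode == "nifti_dir":
        covariates, masks = _stage("ingest")(_load_nifti_cohort)(
            config.input_dir)
    else:
        raise PipelineError(f"unknown input mode {config.input_mode!r}")
    covariates.to_csv(outdir / "covariates.csv")
    if config.save_masks:
        mdir = outdir / "masks"
        mdir.mkdir(exist_ok=True)
        for (pid, side, structure), m in masks.items():
            save_mask(m, mdir / f"{pid}_{side}_{structure}.nii.gz")

    qc_rows = []
    results = PipelineResult(covariates, {}, {}, {}, {}, {}, {}, None, outdir)
    for structure in config.structures:
        fields = {}
        excluded = set()
        for pid in covariates.index:
            for side in ("left", "right"):
                key = (pid, side, structure)
                if key not in masks:
                    continue
                try:
                    f = groom(masks[key], config.iso_spacing,
                              config.smoothing_iterations, config.blur_sigma)
                except PipelineError as e:
                    qc_rows.append({"participant_id": pid, "side": side,
                                    "structure": structure,
                                    "flag": "groom_reject", "detail": str(e)})
                    excluded.add(pid)
                    continue
                if side == "right":
                    f = flip_sagittal(f)
                    fields[(pid, "right_flipped")] = f
                else:
                    fields[(pid, "left")] = f
        # a participant needs both sides
        for pid in covariates.index:
            if ((pid, "left") in fields) != ((pid, "right_flipped") in fields):
                excluded.add(pid)
        fields = {k: v for k, v in fields.items() if k[0] not in excluded}
        if not fields:
            continue
        model = _stage("model")(build_shape_model)(
            fields, structure, config.n_points[structure])
        for (pid, side), frac in model.fallback_fraction.items():
            if frac > 0.05:
                qc_rows.append({"participant_id": pid, "side": side,
                                "structure": structure,
                                "flag": "correspondence_fallback",
                                "detail": f"{frac:.1%}"})
        raw = {(pid, side): masks[(pid, side, structure)]
               for pid in covariates.index if pid not in excluded
               for side in ("left", "right")
               if (pid, side, structure) in masks}
        table = _stage("asymmetry")(build_asymmetry_table)(
            model, fields, raw_masks=raw or None)
        results.models[structure] = model
        results.asymmetry[structure] = table
        save_shape_model(model, outdir / structure / "model")
        save_asymmetry(table, outdir / structure)

        cov_sub = covariates.loc[table.participants()]
        specs = [s for s in default_comparisons(config.sensitivity_mode)
                 if set(s.group_a) | set(s.group_b)
                 <= set(cov_sub["group"].unique())]
        feasible = []
        for s in specs:
            try:
                build_design(cov_sub, s)
            except PipelineError as e:
                qc_rows.append({"participant_id": "", "side": "",
                                "structure": structure,
                                "flag": "comparison_skipped",
                                "detail": str(e)})
                continue
            feasible.append(s)
        specs = feasible
        if specs:
            pw = _stage("stats")(run_family)(
                table, cov_sub, specs, config.alpha, config.pooled_fdr)
            zero_var = pw.groupby("comparison")["zero_variance"].sum()
            for comp, nzv in zero_var.items():
                if nzv:
                    qc_rows.append({"participant_id": "", "side": "",
                                    "structure": structure,
                                    "flag": "zero_variance_points",
                                    "detail": f"{comp}: {int(nzv)}"})
            results.pointwise[structure] = pw
            pw.to_csv(outdir / structure / "pointwise_results.csv",
                      index=False)
            _write_significance_vtk(model, pw, config.alpha,
                                    outdir / structure)
            vol = pd.DataFrame([volume_group_test(table, cov_sub, s)
                                for s in specs])
            results.volume_tests[structure] = vol
            vol.to_csv(outdir / structure / "volume_tests.csv", index=False)
        if "HC" in set(cov_sub["group"]):
            base = run_family(table, cov_sub,
                              [hc_baseline_comparison(
                                  config.sensitivity_mode)],
                              config.alpha, pooled=True)
            results.hc_baseline[structure] = base
            base.to_csv(outdir / structure / "hc_baseline.csv", index=False)

    if config.run_matching:
        results.matching = _run_matching(covariates, config.match_ratio)
        for name, mr in results.matching.items():
            mdf = pd.DataFrame(mr.pairs,
                               columns=["case_id", "control_id"])
            if mr.distances:
                mdf["distance"] = mr.distances
            mdf.to_csv(outdir / f"match_{name}.csv", index=False)
            if mr.balance is not None:
                mr.balance.to_csv(outdir / f"match_{name}_balance.csv")

    results.qc = pd.DataFrame(
        qc_rows, columns=["participant_id", "side", "structure", "flag",
                          "detail"])
    results.qc.to_csv(outdir / "qc_log.csv", index=False)
    manifest = {"version": __version__, "seed": config.seed,
                "config": config.to_dict(),
                "n_participants": int(len(covariates)),
                "excluded": sorted({r["participant_id"] for r in qc_rows
                                    if r["flag"] == "groom_reject"})}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return results


def analyze_structure(covariates: pd.DataFrame,
                      masks: dict,
                      structure: str,
                      n_points: int,
                      iso_spacing: float = DEFAULT_ISO_SPACING,
                      specs=None,
                      alpha: float = ALPHA):
    """In-memory analysis of one structure: groom, model, asymmetry, stats.

    Convenience path without on-disk outputs; returns
    (shape model, asymmetry table, point-wise results or None).
    """
    fields = {}
    for pid in covariates.index:
        left = masks.get((pid, "left", structure))
        right = masks.get((pid, "right", structure))
        if left is None or right is None:
            continue
        fields[(pid, "left")] = groom(left, iso_spacing)
        fields[(pid, "right_flipped")] = flip_sagittal(groom(right,
                                                             iso_spacing))
    model = build_shape_model(fields, structure, n_points)
    table = build_asymmetry_table(model, fields)
    pw = None
    if specs is None:
        specs = [s for s in default_comparisons()
                 if set(s.group_a) | set(s.group_b)
                 <= set(covariates["group"].unique())]
    if specs:
        pw = run_family(table, covariates.loc[table.participants()], specs,
                        alpha)
    return model, table, pw


def _run_matching(covariates: pd.DataFrame, k: int) -> dict[str, MatchResult]:
    """Epilepsy cases vs (a) dementia-only controls on age/sex/dementia type,
    (b) healthy controls on age/sex."""
    cases = list(covariates.index[covariates["group"].isin(
        ["AD_Epi", "nonAD_Epi"])])
    dem_controls = list(covariates.index[covariates["group"].isin(
        ["AD_NoEpi", "nonAD_NoEpi"])])
    hc_controls = list(covariates.index[covariates["group"] == "HC"])
    out = {}
    if cases and dem_controls:
        out["dementia_controls"] = match_controls(
            covariates, cases, dem_controls,
            ["age_at_scan", "sex", "dementia_type"], k)
    if cases and hc_controls:
        out["healthy_controls"] = match_controls(
            covariates, cases, hc_controls, ["age_at_scan", "sex"], k)
    return out


def _write_significance_vtk(model, pointwise: pd.DataFrame, alpha: float,
                            outdir: Path) -> None:
    sig = significance_map(pointwise, alpha)
    for comp in sig["comparison"].unique():
        sub = pointwise[pointwise["comparison"] == comp]
        labels = np.where(sub["q"] < alpha,
                          np.where(sub["beta"] > 0, 1.0, -1.0), 0.0)
        write_vtk_polydata(
            outdir / f"sigmap_{comp}.vtk", model.template_points,
            normals=model.template_normals,
            point_scalars={"beta": sub["beta"].to_numpy(),
                           "q": sub["q"].to_numpy(),
                           "sig_sign": labels})


def qc_report(run_dir: str | Path) -> pd.DataFrame:
    """Summarize per-subject QC flags from a completed (or partial) run."""
    run_dir = Path(run_dir)
    qc_path = run_dir / "qc_log.csv"
    if not qc_path.exists():
        raise PipelineError(f"no QC log found under {run_dir}")
    qc = pd.read_csv(qc_path)
    if qc.empty:
        return pd.DataFrame(columns=["participant_id", "structure", "flag",
                                     "n"])
    return (qc.groupby(["participant_id", "structure", "flag"],
                       dropna=False)
              .size().rename("n").reset_index())
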