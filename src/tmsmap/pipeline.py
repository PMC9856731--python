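"""End-to-end orchestration and the evaluation studies.

``run_pipeline`` chains the whole method on a synthetic subject: head
generation, the 24-placement sulcus-aligned coil grid, one scalar-potential
solve per placement (fields at the three stimulation intensities follow by
linearity), MEP simulation, multiplicative hotspot mapping for both muscles
and both EF metrics, recruitment-curve fits, and — optionally — the two
evaluation studies:

* the sample-count sweep (hotspot area as a function of the number of
  multiplied top-MEP samples), and
* the random-sampling localization study (CoG error of hotspots built from
  k randomly drawn samples whose MEP exceeds 75 / 50 / 25 / 0% of the
  maximum, repeated ``n_repetitions`` times per category).

Everything is a pure function of (config, seed).
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

from .coil import CoilModel, placement_grid, write_placements
from .dose_response import (
    MEPGenConfig,
    calibrate_sigmoid_truth,
    ef_at_fit_point,
    estimate_rmt,
    fit_sigmoid,
    simulate_meps,
)
from .head import HeadGeometry, SyntheticSubject, build_synthetic_head, save_subject
from .hotspot import (
    HotspotMap,
    cog_distance,
    multiply_maps,
    select_top_stimuli,
)
from .solver import HeadSolver
from .surface_metrics import EFSurfaceMap, sample_on_surface, write_surface_map

__all__ = [
    "SamplingCategory",
    "EvaluationResult",
    "PipelineConfig",
    "PipelineError",
    "DEFAULT_CATEGORIES",
    "solve_all_placements",
    "sweep_sample_count",
    "random_category_localization",
    "spawn_cohort",
    "run_pipeline",
]

log = logging.getLogger("tmsmap")


@dataclass(frozen=True)
class SamplingCategory:
    """MEP-amplitude category for the random-sampling study.

    ``label`` names the category (75, 50, 25 or 0) and ``mep_fraction`` is
    the eligibility threshold as a fraction of the per-subject maximum MEP;
    0 admits every suprathreshold record.
    """

    label: int
    mep_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mep_fraction < 1.0):
            raise ValueError("mep_fraction must lie in [0, 1)")


DEFAULT_CATEGORIES = (
    SamplingCategory(75, 0.75),
    SamplingCategory(50, 0.50),
    SamplingCategory(25, 0.25),
    SamplingCategory(0, 0.0),
)


@dataclass
class EvaluationResult:
    subject_id: str
    category: int
    repetition: int
    k_samples: int
    cog_error_mm: float
    hotspot_area_mm2: float


@dataclass
class PipelineConfig:
    """Configuration of a full mapping run (see module docstring)."""

    geometry: HeadGeometry = field(default_factory=HeadGeometry)
    coil: CoilModel = field(default_factory=CoilModel)
    seed: int = 0
    n_anchors: int = 8
    anchor_spacing_mm: float = 5.0
    shifts_mm: tuple[float, ...] = (-5.0, 0.0, 5.0)
    intensities_pct_mso: tuple[float, ...] = (35.0, 45.0, 55.0)
    eval_intensity_pct_mso: float = 55.0
    trials_per_placement: int = 5
    noise_sigma_log: float = 0.3
    noise_floor_mv: float = 0.02
    drive_metric: str = "strength"
    sigmoid_threshold_fraction: float = 0.49
    k_by_metric: tuple[tuple[str, int], ...] = (("strength", 5), ("normal", 3))
    mep_reduce: str = "median"
    solver_tol: float = 1e-6
    preconditioner: str = "auto"
    run_sweep: bool = True
    sweep_k_max: int = 8
    run_categories: bool = False
    n_repetitions: int = 100
    category_k: int = 5
    save_maps: bool = False


class PipelineError(RuntimeError):
    """A stage failed; names the stage and lists completed artifacts."""

    def __init__(self, stage: str, artifacts: dict, cause: Exception):
        super().__init__(
            f"pipeline stage {stage!r} failed: {cause} "
            f"(completed artifacts: {sorted(artifacts)})"
        )
        self.stage = stage
        self.artifacts = dict(artifacts)
        self.__cause__ = cause


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def solve_all_placements(
    subject: SyntheticSubject,
    placements,
    coil: CoilModel | None = None,
    tol: float = 1e-6,
    preconditioner: str = "auto",
    use_cache: bool = True,
) -> dict[str, EFSurfaceMap]:
    """Solve every placement at 100 %MSO and sample the cortex.

    Returns ``placement_id -> EFSurfaceMap`` (at 100 %MSO; scale with
    :meth:`EFSurfaceMap.scaled` for other intensities).  Fine grids
    (voxel <= 1.25 mm) warm-start from a 2x coarser companion model.
    """
    import dataclasses as _dc

    coarse = None
    if subject.head.voxel_size_mm <= 1.25:
        cg = _dc.replace(
            subject.geometry, voxel_size_mm=2.0 * subject.head.voxel_size_mm
        )
        coarse = build_synthetic_head(cg, seed=subject.seed).head
    solver = HeadSolver(
        subject.head, coil, tol=tol, preconditioner=preconditioner,
        use_cache=use_cache, coarse_head=coarse,
    )
    brain = subject.head.labels >= 4
    maps: dict[str, EFSurfaceMap] = {}
    for p in placements:
        t0 = time.perf_counter()
        ef = solver.solve(p)
        maps[p.placement_id] = sample_on_surface(
            ef, subject.surface, p.placement_id, sample_mask=brain
        )
        log.info("solved %s in %.1f s", p.placement_id, time.perf_counter() - t0)
    return maps


def _maps_at(maps100: dict[str, EFSurfaceMap], ids, pct: float) -> list[EFSurfaceMap]:
    return [maps100[i].scaled(pct) for i in ids]


def sweep_sample_count(
    subject: SyntheticSubject,
    maps100: dict[str, EFSurfaceMap],
    records: pd.DataFrame,
    muscle: str,
    metric: str,
    k_range=range(1, 9),
    intensity_pct_mso: float = 55.0,
    reduce: str = "median",
) -> pd.DataFrame:
    """Hotspot area (and CoG) as a function of the number of top samples."""
    rows = []
    for k in k_range:
        ids = select_top_stimuli(records, muscle, k, intensity_pct_mso, reduce)
        hmap = multiply_maps(
            _maps_at(maps100, ids, intensity_pct_mso), metric, subject.surface, muscle
        )
        rows.append((muscle, metric, k, hmap.area_mm2, *hmap.cog))
    return pd.DataFrame(
        rows, columns=["muscle", "metric", "k", "area_mm2", "cog_x", "cog_y", "cog_z"]
    )


def random_category_localization(
    subject: SyntheticSubject,
    maps100: dict[str, EFSurfaceMap],
    records: pd.DataFrame,
    category: SamplingCategory,
    muscle: str,
    metric: str = "strength",
    n_repetitions: int = 100,
    k: int = 5,
    seed: int = 0,
    intensity_pct_mso: float = 55.0,
    subject_id: str = "s0",
) -> pd.DataFrame:
    """Localization error of hotspots built from randomly drawn samples.

    Trials whose MEP exceeds ``category.mep_fraction`` of the maximum MEP
    are eligible; each repetition draws ``k`` of them uniformly without
    replacement (placements may repeat across trials, and repeated
    placements then enter the product repeatedly).  Errors are measured
    against the reference CoG obtained from the ``k`` highest-MEP
    placements.  Returns one row per repetition; an empty frame (with a
    logged warning) when fewer than ``k`` trials are eligible.

    A dedicated random stream is derived from (seed, subject, category), so
    adding categories does not perturb the draws of the others.
    """
    df = records[
        (records["muscle"] == muscle)
        & (records["intensity_pct_mso"] == intensity_pct_mso)
    ].reset_index(drop=True)
    if df.empty:
        raise ValueError("no records for the requested muscle/intensity")
    mep_max = df["mep_pp"].max()
    eligible = df[df["mep_pp"] > category.mep_fraction * mep_max]
    if len(eligible) < k:
        log.warning(
            "category %d%%: only %d eligible records (< k=%d), skipped",
            category.label, len(eligible), k,
        )
        return pd.DataFrame(
            columns=[f.name for f in dataclasses.fields(EvaluationResult)]
        )

    ref_ids = select_top_stimuli(records, muscle, k, intensity_pct_mso, reduce="max")
    ref = multiply_maps(
        _maps_at(maps100, ref_ids, intensity_pct_mso), metric, subject.surface, muscle
    )

    rng = np.random.default_rng([seed, subject.seed, category.label])
    rows = []
    elig_pids = eligible["placement_id"].to_numpy()
    for rep in range(1, n_repetitions + 1):
        draw = rng.choice(len(elig_pids), size=k, replace=False)
        ids = list(elig_pids[draw])
        hmap = multiply_maps(
            _maps_at(maps100, ids, intensity_pct_mso), metric, subject.surface, muscle
        )
        rows.append(
            EvaluationResult(
                subject_id=subject_id,
                category=category.label,
                repetition=rep,
                k_samples=k,
                cog_error_mm=cog_distance(hmap, ref),
                hotspot_area_mm2=hmap.area_mm2,
            )
        )
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def spawn_cohort(
    template: SyntheticSubject, n_subjects: int, seed: int = 0
) -> list[SyntheticSubject]:
    """Cohort of subjects sharing the template head and surface topology.

    Inter-subject variability is represented by jittered truth-site
    positions along the fold lip and independent MEP noise streams; the
    shared head means the (placement-wise identical) field solves can be
    reused across the cohort, and the shared topology gives the identity
    vertex correspondence the group analysis assumes.
    """
    from scipy.spatial import cKDTree

    geom = template.geometry
    tree = cKDTree(template.surface.vertices)
    s_truth = geom.truth_lip_fraction * geom.fold_wavelength_mm
    cohort = []
    rng = np.random.default_rng([seed, 1234])
    for i in range(n_subjects):
        jitter = rng.uniform(-3.0, 3.0)  # mm along the sulcus
        sites: dict[str, int] = {}
        taken: set[int] = set()
        for muscle, t_off in (
            ("FDI", jitter - geom.truth_separation_mm / 2.0),
            ("ADM", jitter + geom.truth_separation_mm / 2.0),
        ):
            u = geom.direction_from_coords(s_truth, t_off)
            d = float(geom.fold_displacement(np.array(s_truth), np.array(t_off)))
            target = u * (geom.gray_radius_mm + d - template.sampling_depth_mm)
            _, cand = tree.query(target, k=4)
            idx = next(int(c) for c in np.atleast_1d(cand) if int(c) not in taken)
            taken.add(idx)
            sites[muscle] = idx
        cohort.append(
            SyntheticSubject(
                head=template.head,
                surface=template.surface,
                geometry=geom,
                truth_sites=sites,
                sigmoid_truth=dict(template.sigmoid_truth),
                noise_sigma_log=template.noise_sigma_log,
                seed=int(rng.integers(0, 2**31 - 1)),
                regions=template.regions,
                sampling_depth_mm=template.sampling_depth_mm,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full mapping pipeline; return (and optionally write) a report.

    The report is a plain JSON-serializable dict and a pure function of the
    configuration (including its seed); with ``out_dir`` the intermediate
    artifacts (head model, placements, records, hotspot summaries) are
    written alongside ``report.json``.
    """
    artifacts: dict[str, str] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "synth-head"
    try:
        subject = build_synthetic_head(
            config.geometry, seed=config.seed, noise_sigma_log=config.noise_sigma_log
        )
        if out is not None:
            for k, p in save_subject(subject, out).items():
                artifacts[k] = str(p)

        stage = "place-coils"
        placements = placement_grid(
            subject.sulcus_scalp_polyline(),
            n_anchors=config.n_anchors,
            spacing_mm=config.anchor_spacing_mm,
            shifts_mm=config.shifts_mm,
            intensity_pct_mso=config.eval_intensity_pct_mso,
            projector=subject.scalp_project,
        )
        if out is not None:
            write_placements(placements, out / "placements.csv")
            artifacts["placements"] = str(out / "placements.csv")

        stage = "solve"
        maps100 = solve_all_placements(
            subject,
            placements,
            config.coil,
            tol=config.solver_tol,
            preconditioner=config.preconditioner,
        )
        if out is not None and config.save_maps:
            (out / "maps").mkdir(exist_ok=True)
            for pid, m in maps100.items():
                write_surface_map(m, out / "maps" / f"map_{pid}.csv")
            artifacts["maps"] = str(out / "maps")

        stage = "simulate-meps"
        calibrate_sigmoid_truth(
            subject,
            maps100,
            threshold_fraction=config.sigmoid_threshold_fraction,
            drive_metric=config.drive_metric,
        )
        gen = MEPGenConfig(
            sigmoid_truth=subject.sigmoid_truth,
            noise_sigma_log=config.noise_sigma_log,
            noise_floor_mv=config.noise_floor_mv,
            drive_metric=config.drive_metric,
            seed=config.seed,
        )
        records = simulate_meps(
            subject,
            maps100,
            gen,
            intensities_pct_mso=config.intensities_pct_mso,
            trials_per_placement=config.trials_per_placement,
        )
        if out is not None:
            records.to_csv(out / "records.csv", index=False)
            artifacts["records"] = str(out / "records.csv")

        stage = "map"
        muscles = sorted(subject.truth_sites)
        hotspots: dict[str, dict[str, HotspotMap]] = {m: {} for m in muscles}
        for muscle in muscles:
            for metric, k in config.k_by_metric:
                ids = select_top_stimuli(
                    records, muscle, k, config.eval_intensity_pct_mso,
                    reduce=config.mep_reduce,
                )
                hotspots[muscle][metric] = multiply_maps(
                    _maps_at(maps100, ids, config.eval_intensity_pct_mso),
                    metric,
                    subject.surface,
                    muscle,
                )

        stage = "fit"
        fits: dict[str, dict[str, dict]] = {m: {} for m in muscles}
        for muscle in muscles:
            for metric, _k in config.k_by_metric:
                efmax = ef_at_fit_point(maps100, hotspots[muscle][metric], metric)
                efmax = efmax.rename(columns={"stimulus_id": "placement_id"})
                pairs = records[records["muscle"] == muscle].merge(
                    efmax[["placement_id", "ef_max"]], on="placement_id"
                )
                pairs["ef_max"] = (
                    pairs["ef_max"] * pairs["intensity_pct_mso"] / 100.0
                )
                fit = fit_sigmoid(
                    pairs["ef_max"].to_numpy(), pairs["mep_pp"].to_numpy()
                )
                fits[muscle][metric] = {
                    "a": fit.a, "b": fit.b, "c": fit.c, "r2": fit.r2,
                    "ef_threshold": fit.ef_threshold,
                    "ef_saturation": fit.ef_saturation,
                    "divergent": fit.divergent,
                    "reasons": list(fit.reasons),
                    "n_obs": fit.n_obs,
                }

        stage = "evaluate"
        rmt = {
            m: dataclasses.asdict(estimate_rmt(records, m)) for m in muscles
        }
        sweep_rows = []
        if config.run_sweep:
            for muscle in muscles:
                for metric, _k in config.k_by_metric:
                    sweep_rows.append(
                        sweep_sample_count(
                            subject, maps100, records, muscle, metric,
                            k_range=range(1, config.sweep_k_max + 1),
                            intensity_pct_mso=config.eval_intensity_pct_mso,
                            reduce=config.mep_reduce,
                        )
                    )
        sweep = pd.concat(sweep_rows, ignore_index=True) if sweep_rows else None

        categories = {}
        if config.run_categories:
            for muscle in muscles:
                categories[muscle] = {}
                for cat in DEFAULT_CATEGORIES:
                    df = random_category_localization(
                        subject, maps100, records, cat, muscle,
                        metric="strength",
                        n_repetitions=config.n_repetitions,
                        k=config.category_k,
                        seed=config.seed,
                        intensity_pct_mso=config.eval_intensity_pct_mso,
                    )
                    mep_max = records[
                        (records["muscle"] == muscle)
                        & (records["intensity_pct_mso"] == config.eval_intensity_pct_mso)
                    ]["mep_pp"].max()
                    n_eligible = int(
                        (
                            records[
                                (records["muscle"] == muscle)
                                & (
                                    records["intensity_pct_mso"]
                                    == config.eval_intensity_pct_mso
                                )
                            ]["mep_pp"]
                            > cat.mep_fraction * mep_max
                        ).sum()
                    )
                    categories[muscle][str(cat.label)] = {
                        "n_eligible": n_eligible,
                        "n_repetitions": int(len(df)),
                        "median_error_mm": (
                            float(df["cog_error_mm"].median()) if len(df) else None
                        ),
                        "median_area_mm2": (
                            float(df["hotspot_area_mm2"].median()) if len(df) else None
                        ),
                    }
    except Exception as exc:  # noqa: BLE001
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, artifacts, exc) from exc

    report = {
        "config": _jsonable(dataclasses.asdict(config)),
        "n_placements": len(placements),
        "n_solves": len(placements),
        "n_records": int(len(records)),
        "records_per_intensity": int(
            len(records) // (len(config.intensities_pct_mso) * len(muscles))
        ),
        "truth_sites": {
            m: {
                "vertex": int(subject.truth_sites[m]),
                "position_mm": _jsonable(subject.truth_position(m)),
            }
            for m in muscles
        },
        "sigmoid_truth": _jsonable(subject.sigmoid_truth),
        "rmt": _jsonable(rmt),
        "hotspots": {
            m: {
                metric: {
                    "k": h.k_samples,
                    "area_mm2": h.area_mm2,
                    "cog_mm": _jsonable(h.cog),
                    "stimulus_ids": list(h.stimulus_ids),
                    "truth_error_mm": float(
                        np.linalg.norm(h.cog - subject.truth_position(m))
                    ),
                }
                for metric, h in hotspots[m].items()
            }
            for m in muscles
        },
        "cog_distance_mm": {
            metric: cog_distance(hotspots[muscles[0]][metric], hotspots[muscles[1]][metric])
            for metric, _k in config.k_by_metric
        }
        if len(muscles) == 2
        else {},
        "fits": _jsonable(fits),
        # metric-comparison harness: average explanatory power of the two
        # EF metrics across muscles (no fixed target; shape inspection)
        "r2_by_metric": {
            metric: float(np.mean([fits[m][metric]["r2"] for m in muscles]))
            for metric, _k in config.k_by_metric
        },
        "sweep": (
            _jsonable(sweep.to_dict(orient="list")) if sweep is not None else None
        ),
        "categories": _jsonable(categories),
    }

    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        artifacts["report"] = str(out / "report.json")
        if sweep is not None:
            sweep.to_csv(out / "sweep.csv", index=False)
    report["artifacts"] = artifacts
    return report
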