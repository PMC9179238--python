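"""Pipeline orchestration: simulate -> gate -> trend/episodes -> cluster.

Stages can run fully in memory (:func:`gate_study`, used by analyses and
tests) or against a directory layout of FCS files and CSV tables
(:func:`run_pipeline`), in which case each stage consumes only the
previous stage's outputs and a run manifest with content digests is
written last.  Every CSV gains a ``.schema.json`` sidecar declaring its
columns.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import StudyConfig
from .episodes import detect_episodes, episode_contrast, marker_correlation
from .fcsio import read_fcs, write_fcs
from .gating import HRDCCResult, build_tree, compare_gating, results_frame, run_hrdcc
from .longitudinal import fit_poly3, fit_spline4, per_animal_summary, rout_outliers
from .multivariate import assemble_matrix, auroc_one_vs_rest, pca, splsda_fit
from .simulate import StudySet, simulate_study

STAGES = ("simulate", "gate", "trend", "episodes", "cluster")


# ---------------------------------------------------------------------------
# in-memory study gating
# ---------------------------------------------------------------------------

def gate_study(study: StudySet, mode: str = "both",
               events_per_sample: int | None = None,
               ) -> dict[str, list[HRDCCResult]]:
    """Synthesise and gate every sample of a study, returning per-mode
    result lists.  Events are generated per sample and discarded, so the
    footprint stays small."""
    modes = ("reference", "auto") if mode == "both" else (mode,)
    trees = {m: build_tree(m, study.config) for m in ("milk", "blood")}
    out: dict[str, list[HRDCCResult]] = {m: [] for m in modes}
    for row in study.samples.itertuples():
        em = study.events_for(row.sample_id, n_events=events_per_sample)
        for m in modes:
            out[m].append(run_hrdcc(em, trees[row.matrix], mode=m))
    return out


# ---------------------------------------------------------------------------
# disk-based stages
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)
    schema = {"columns": [{"name": c, "dtype": str(df[c].dtype)} for c in df.columns]}
    path.with_suffix(path.suffix + ".schema.json").write_text(
        json.dumps(schema, indent=2))


def stage_simulate(config: StudyConfig, out_dir: Path, seed: int) -> StudySet:
    out_dir.mkdir(parents=True, exist_ok=True)
    fcs_dir = out_dir / "fcs"
    fcs_dir.mkdir(exist_ok=True)
    study = simulate_study(config, seed=seed)
    for row in study.samples.itertuples():
        em = study.events_for(row.sample_id)
        write_fcs(em, fcs_dir / f"{row.sample_id}.fcs")
    _write_csv(study.samples[["sample_id", "animal_id", "dim", "matrix"]],
               out_dir / "samples.csv")
    _write_csv(study.biomarkers, out_dir / "biomarkers.csv")
    _write_csv(study.episodes_frame(), out_dir / "episodes_true.csv")
    _write_csv(study.truth_frame(), out_dir / "truth.csv")
    config.save(out_dir / "config.json")
    return study


def stage_gate(out_dir: Path, mode: str = "both") -> pd.DataFrame:
    samples_path = out_dir / "samples.csv"
    if not samples_path.exists():
        raise FileNotFoundError(
            "gate stage: missing samples.csv (run the simulate stage first)")
    samples = pd.read_csv(samples_path)
    config = StudyConfig.load(out_dir / "config.json")
    trees = {m: build_tree(m, config) for m in ("milk", "blood")}
    modes = ("reference", "auto") if mode == "both" else (mode,)
    results: dict[str, list[HRDCCResult]] = {m: [] for m in modes}
    for row in samples.itertuples():
        fcs_path = out_dir / "fcs" / f"{row.sample_id}.fcs"
        if not fcs_path.exists():
            raise FileNotFoundError(f"gate stage: missing FCS file {fcs_path}")
        em = read_fcs(fcs_path, load_truth=False)
        for m in modes:
            results[m].append(run_hrdcc(em, trees[row.matrix], mode=m))
    hrdcc = pd.concat([results_frame(results[m]) for m in modes], ignore_index=True)
    _write_csv(hrdcc, out_dir / "hrdcc.csv")
    if len(modes) == 2:
        cmp = compare_gating(results["reference"], results["auto"])
        _write_csv(pd.DataFrame([{
            "n_gates": cmp.n_gates, "r": cmp.r, "slope": cmp.slope,
            "intercept": cmp.intercept, "p_value": cmp.p_value}]),
            out_dir / "gate_comparison.csv")
    return hrdcc


def _hrdcc_series(out_dir: Path) -> pd.DataFrame:
    path = out_dir / "hrdcc.csv"
    if not path.exists():
        raise FileNotFoundError("missing hrdcc.csv (run the gate stage first)")
    hrdcc = pd.read_csv(path)
    samples = pd.read_csv(out_dir / "samples.csv")
    use = hrdcc[(hrdcc.denominator == "parent")
                & (hrdcc["mode"] == sorted(hrdcc["mode"].unique())[0])]
    return use.merge(samples, on="sample_id")


def stage_trend(out_dir: Path, q: float = 0.01) -> None:
    series = _hrdcc_series(out_dir)
    trend_rows, summary_rows = [], []
    for (animal, matrix, node), grp in series.groupby(
            ["animal_id", "matrix", "node"]):
        grp = grp.sort_values("dim")
        dims = grp.dim.to_numpy(float)
        vals = grp.percent.to_numpy(float)
        if len(dims) < 10:
            continue
        flags = rout_outliers(dims, vals, q)
        spl = fit_spline4(dims, vals, flags)
        ply = fit_poly3(dims, vals, flags)
        for d, v, fs, fp, fl in zip(dims, vals, spl.fitted, ply.fitted, flags):
            trend_rows.append((animal, matrix, node, int(d), v, fs, fp, bool(fl)))
        mean, sd, n = per_animal_summary(vals[~flags])
        summary_rows.append((animal, matrix, node, mean, sd, n))
    _write_csv(pd.DataFrame(trend_rows, columns=[
        "animal_id", "matrix", "node", "dim", "percent",
        "fitted_spline4", "fitted_poly3", "outlier"]), out_dir / "trends.csv")
    _write_csv(pd.DataFrame(summary_rows, columns=[
        "animal_id", "matrix", "node", "mean", "sd", "n"]),
        out_dir / "animal_summary.csv")


def stage_episodes(out_dir: Path) -> None:
    bio_path = out_dir / "biomarkers.csv"
    if not bio_path.exists():
        raise FileNotFoundError("episodes stage: missing biomarkers.csv")
    biomarkers = pd.read_csv(bio_path)
    config = StudyConfig.load(out_dir / "config.json")
    series = _hrdcc_series(out_dir)
    threshold = config.haptoglobin_threshold
    ep_rows, contrast_rows, corr_rows = [], [], []
    hp = biomarkers[biomarkers.analyte == "haptoglobin"]
    for animal, grp in hp.groupby("animal_id"):
        grp = grp.sort_values("dim")
        eps = detect_episodes(grp.dim.to_numpy(), grp.value.to_numpy(),
                              threshold, animal_id=animal)
        for ep in eps:
            ep_rows.append((animal, ep.start, ep.end, ep.peak_haptoglobin,
                            ep.n_visits))
        for node in ("gd_t_cells", "cd4_t_cells", "immature_granulocytes"):
            cell = series[(series.animal_id == animal) & (series.matrix == "milk")
                          & (series.node == node)].sort_values("dim")
            if cell.empty:
                continue
            for detrend in (False, True):
                con = episode_contrast(cell.dim.to_numpy(),
                                       cell.percent.to_numpy(), eps,
                                       population=node, detrend=detrend)
                contrast_rows.append((animal, node, detrend, con.in_mean,
                                      con.out_mean, con.difference, con.p_value,
                                      con.n_in, con.n_out, con.reason))
        for matrix in ("milk", "blood"):
            imm = series[(series.animal_id == animal) & (series.matrix == matrix)
                         & (series.node == "immature_granulocytes")]
            paired = imm.merge(grp, on="dim", suffixes=("", "_hp"))
            if len(paired) >= 10:
                r, (lo, hi), p = marker_correlation(
                    paired.value.to_numpy(), paired.percent.to_numpy())
                corr_rows.append((animal, matrix, r, lo, hi, p, len(paired)))
    _write_csv(pd.DataFrame(ep_rows, columns=[
        "animal_id", "start", "end", "peak_haptoglobin", "n_visits"]),
        out_dir / "episodes.csv")
    _write_csv(pd.DataFrame(contrast_rows, columns=[
        "animal_id", "population", "detrended", "in_mean", "out_mean",
        "difference", "p_value", "n_in", "n_out", "reason"]),
        out_dir / "episode_contrasts.csv")
    _write_csv(pd.DataFrame(corr_rows, columns=[
        "animal_id", "matrix", "r", "ci_low", "ci_high", "p_value", "n"]),
        out_dir / "marker_correlations.csv")


def stage_cluster(out_dir: Path, n_components: int = 2, keep_x: int = 5) -> None:
    hrdcc = pd.read_csv(out_dir / "hrdcc.csv")
    mode = sorted(hrdcc["mode"].unique())[0]
    hrdcc = hrdcc[hrdcc["mode"] == mode]
    samples = pd.read_csv(out_dir / "samples.csv")
    biomarkers = pd.read_csv(out_dir / "biomarkers.csv")
    pca_rows, score_rows, auroc_rows, loading_rows = [], [], [], []
    for scope in ("all", "milk", "blood", "lab"):
        pm = assemble_matrix(hrdcc, biomarkers, samples, scope)
        scores, loadings, evr = pca(pm, n_components)
        for (idx, meta_row), sc in zip(pm.meta.iterrows(), scores):
            pca_rows.append((scope, meta_row.animal_id, meta_row.dim,
                             *sc[:n_components]))
        model = splsda_fit(pm, n_components=n_components,
                           keep_x=min(keep_x, len(pm.feature_names)))
        for (idx, meta_row), sc in zip(pm.meta.iterrows(), model.scores):
            score_rows.append((scope, meta_row.animal_id, meta_row.dim,
                               *sc[:n_components]))
        for phase in model.classes:
            auroc_rows.append((scope, int(phase),
                               auroc_one_vs_rest(model, pm, phase=int(phase))))
        for j, name in enumerate(pm.feature_names):
            if np.any(model.weights[j] != 0):
                loading_rows.append((scope, name, *model.weights[j]))
    comp_cols = [f"comp{i+1}" for i in range(n_components)]
    _write_csv(pd.DataFrame(pca_rows, columns=["scope", "animal_id", "dim", *comp_cols]),
               out_dir / "pca_scores.csv")
    _write_csv(pd.DataFrame(score_rows, columns=["scope", "animal_id", "dim", *comp_cols]),
               out_dir / "splsda_scores.csv")
    _write_csv(pd.DataFrame(auroc_rows, columns=["scope", "phase", "auroc"]),
               out_dir / "auroc.csv")
    _write_csv(pd.DataFrame(loading_rows, columns=["scope", "feature", *comp_cols]),
               out_dir / "loadings.csv")


# ---------------------------------------------------------------------------
# manifest and the full run
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[str]
    digests: dict[str, str]
    started: float
    finished: float


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: StudyConfig, stages: list[str] | tuple[str, ...],
                 out_dir: str | Path, seed: int = 1) -> RunManifest:
    """Run a contiguous prefix of the stage sequence against ``out_dir``."""
    stages = list(stages)
    if stages != list(STAGES[:len(stages)]) and set(stages) != set(STAGES):
        raise ValueError(f"stages must be a contiguous prefix of {STAGES}")
    out_dir = Path(out_dir)
    started = time.time()
    for stage in stages:
        if stage == "simulate":
            stage_simulate(config, out_dir, seed)
        elif stage == "gate":
            stage_gate(out_dir)
        elif stage == "trend":
            stage_trend(out_dir)
        elif stage == "episodes":
            stage_episodes(out_dir)
        elif stage == "cluster":
            stage_cluster(out_dir)
    digests = {p.name: _digest(p) for p in sorted(out_dir.glob("*.csv"))}
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()).hexdigest()
    manifest = RunManifest(cfg_hash, seed, __version__, stages, digests,
                           started, time.time())
    (out_dir / "manifest.json").write_text(json.dumps(manifest.__dict__, indent=2))
    return manifest


def make_fixture(scale: str, out_dir: str | Path, seed: int = 1,
                 ) -> tuple[StudyConfig, Path]:
    """Write a simulation fixture directory.

    ``tiny`` = 2 animals, ~10 visits each, 5,000 events per sample (for
    fast tests); ``default`` = the full 8-animal study.
    """
    out_dir = Path(out_dir)
    if scale == "tiny":
        config = StudyConfig(n_animals=2, events_per_sample=5_000,
                             lactation_days_range=(49, 49), dropout_prob=0.0)
        config = _truncate_schedule(config)
    elif scale == "default":
        config = StudyConfig()
    else:
        raise ValueError(f"unknown fixture scale {scale!r}")
    stage_simulate(config, out_dir, seed)
    return config, out_dir


def _truncate_schedule(config: StudyConfig) -> StudyConfig:
    # tiny fixture: twice-weekly until DIM 21, weekly to 49 -> 11 visits
    config.twice_weekly_until = 21
    return config
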