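"""End-to-end orchestration: simulate -> preprocess -> fit -> decode ->
metrics -> maps -> group statistics.

The model is fit once on the envelopes of all subjects (all groups)
concatenated in time, mirroring the primary group-level design; per-subject
paths, metrics and maps are then cut from the concatenated axis at the
recorded subject boundaries.  Decoded states are matched to the planted
topographies by optimal assignment on the group-average partial-correlation
map, so recovered metrics can be reported per planted state.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthgen
from .config import RunConfig
from .envelope import normalize_concatenate, raw_to_envelope
from .groupstats import (adjacency_from_topographies, bartlett_test,
                         fwe_map_test, permutation_ttest)
from .hmm import HMMParams, fit_hmm, match_states, state_indicators, viterbi_decode
from .maps import GLMDesign, average_maps, build_design, partial_correlation_map
from .metrics import TemporalMetrics, compute_temporal_metrics, metrics_table

__all__ = ["PipelineResult", "analyze_cohorts", "run_pipeline", "subject_map"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the downstream stages and reports need from one run."""

    params: HMMParams
    concatenated: np.ndarray
    boundaries: np.ndarray
    paths: list[np.ndarray]            # decoded, per subject, 1..K
    gt_paths: list[np.ndarray]         # planted, trimmed to the decoded axis
    groups: list[str]
    metrics: list[TemporalMetrics]
    subject_maps: list[np.ndarray]     # (M, K) per subject
    group_map: np.ndarray              # (M, K) mean over all subjects
    planted_to_decoded: np.ndarray     # 1-based: planted k -> decoded label
    topographies: np.ndarray
    fs_env: float

    def group_mean(self, metric: str, planted_state: int,
                   group: str | None = None) -> float:
        """Group-mean FO / FC / LT_ms of the decoded state matched to a
        planted state label."""
        decoded = self.planted_to_decoded[planted_state - 1]
        vals = [getattr(m, metric)[decoded - 1] for m in self.metrics
                if group is None or m.group == group]
        return float(np.nanmean(vals))


def subject_map(indicators: np.ndarray, envelope: np.ndarray) -> np.ndarray:
    """Per-subject partial-correlation map, tolerant to absent states.

    States a subject never visits have zero-variance indicator columns;
    they are dropped from the regression and reported as zero coefficients.
    """
    ind = np.asarray(indicators, dtype=float)
    present = ind.std(axis=0) > 0
    out = np.zeros((envelope.shape[1], ind.shape[1]))
    if present.sum() == 0:
        return out
    sub = ind[:, present]
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0)
    design = GLMDesign(raw=sub, matrix=z,
                       labels=[str(i + 1) for i in np.flatnonzero(present)])
    out[:, present] = partial_correlation_map(design, envelope)
    return out


def _preset_config(name: str, cfg: RunConfig, seed: int) -> synthgen.SynthConfig:
    if name in ("ch_default", "surrogate"):
        return synthgen.ch_default(cfg.n_subjects, cfg.duration_s, seed)
    return synthgen.ad_default(cfg.n_subjects, cfg.duration_s, seed)


def analyze_cohorts(
    cohorts: list[tuple[list[np.ndarray], synthgen.GroundTruth]],
    fs_raw: float,
    K: int,
    n_restarts: int = 10,
    seed: int = 0,
    band: str = "wide",
    orthogonalize: bool = True,
    trim_s: float = 1.0,
    fs_env: float = 20.0,
    max_iter: int = 500,
    restart_iter: int = 15,
) -> PipelineResult:
    """Run preprocessing, model fitting, decoding, metrics and maps on one
    or more simulated cohorts (all subjects enter a single concatenated fit).
    """
    envs, gt_paths, groups = [], [], []
    topo = cohorts[0][1].topographies
    trim = int(round(trim_s * fs_env))
    t0 = time.perf_counter()
    for raws, gt in cohorts:
        for raw, path, grp in zip(raws, gt.paths, gt.groups):
            envs.append(raw_to_envelope(raw, fs_raw, band, fs_env,
                                        orthogonalize=orthogonalize,
                                        trim_s=trim_s))
            gt_paths.append(path[trim:-trim] if trim else path)
            groups.append(grp)
    concat, bounds = normalize_concatenate(envs)
    log.info("preprocessing: %d subjects, T=%d, M=%d (%.1fs)",
             len(envs), concat.shape[0], concat.shape[1],
             time.perf_counter() - t0)

    t0 = time.perf_counter()
    params = fit_hmm(concat, K, n_restarts=n_restarts, seed=seed,
                     max_iter=max_iter, restart_iter=restart_iter)
    log.info("HMM fit: K=%d, score=%.1f, %d iterations (%.1fs)",
             K, params.score, len(params.trace), time.perf_counter() - t0)

    full_path = viterbi_decode(params, concat)
    starts = np.concatenate(([0], bounds[:-1]))
    paths = [full_path[s:e] for s, e in zip(starts, bounds)]

    metrics, subject_maps = [], []
    for i, (path, grp) in enumerate(zip(paths, groups)):
        metrics.append(compute_temporal_metrics(path, K, fs_env,
                                                subject=f"sub{i:03d}", group=grp))
        ind = state_indicators(path, K)
        subject_maps.append(subject_map(ind, concat[starts[i]:bounds[i]]))
    group_map = average_maps(subject_maps)
    perm = match_states(topo.T, group_map)  # planted k -> decoded label
    return PipelineResult(
        params=params, concatenated=concat, boundaries=bounds, paths=paths,
        gt_paths=gt_paths, groups=groups, metrics=metrics,
        subject_maps=subject_maps, group_map=group_map,
        planted_to_decoded=perm, topographies=topo, fs_env=fs_env,
    )


def _group_stats(result: PipelineResult, cfg: RunConfig,
                 seed: int) -> pd.DataFrame:
    """Permutation/Bartlett tests on FO and LT per state, two groups."""
    names = sorted(set(result.groups))
    ga, gb = names[0], names[1]
    ia = [i for i, g in enumerate(result.groups) if g == ga]
    ib = [i for i, g in enumerate(result.groups) if g == gb]
    rows = []
    for metric in ("FO", "LT_ms"):
        for k in range(result.params.K):
            va = np.array([getattr(result.metrics[i], metric)[k] for i in ia])
            vb = np.array([getattr(result.metrics[i], metric)[k] for i in ib])
            va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
            if va.size < 2 or vb.size < 2:
                continue
            try:
                res = permutation_ttest(va, vb, n_perm=cfg.n_perm, seed=seed + k)
                bstat, bp = bartlett_test(va, vb)
            except ValueError:
                continue
            rows.append({"metric": metric, "state": k + 1, "t": res.t,
                         "p_perm": res.p, "bartlett_chi2": bstat,
                         "bartlett_p": bp})
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Execute the configured run and write all result tables.

    Outputs in ``outdir``: ``metrics.tsv`` (one row per subject x state),
    ``group_map.tsv`` and per-group maps, ``stats.tsv`` and ``map_fwe.tsv``
    when two groups are present, and ``manifest.json`` recording every
    parameter and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    sim_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(cfg.presets) + 2)]
    cohorts = []
    surrogate_used = False
    for name, s in zip(cfg.presets, sim_seeds):
        scfg = _preset_config(name, cfg, s)
        raws, gt = synthgen.simulate_cohort(scfg)
        if name == "surrogate":
            surrogate_used = True
            raws = [surr.T for surr in
                    (synthgen.simulate_surrogate(r.T, 1, seed=s + i)[0]
                     for i, r in enumerate(raws))]
            gt.groups = ["surrogate"] * len(raws)
        cohorts.append((raws, gt))
        log.info("simulated preset %s: %d subjects, %.0f s", name,
                 scfg.n_subjects, scfg.duration_s)

    result = analyze_cohorts(
        cohorts, fs_raw=200.0, K=cfg.K, n_restarts=cfg.n_restarts,
        seed=sim_seeds[-2], band=cfg.band, orthogonalize=cfg.orthogonalize,
        trim_s=cfg.trim_s, max_iter=cfg.max_iter,
        restart_iter=cfg.restart_iter)

    table = metrics_table(result.metrics)
    table.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    np.savetxt(outdir / "group_map.tsv", result.group_map,
               fmt="%.8g", delimiter="\t")

    groups = sorted(set(result.groups))
    if len(groups) == 2:
        stats = _group_stats(result, cfg, sim_seeds[-1])
        stats.to_csv(outdir / "stats.tsv", sep="\t", index=False)
        adj = adjacency_from_topographies(result.topographies)
        ia = [i for i, g in enumerate(result.groups) if g == groups[0]]
        ib = [i for i, g in enumerate(result.groups) if g == groups[1]]
        rows = []
        for k in range(cfg.K):
            ma = np.stack([result.subject_maps[i][:, k] for i in ia])
            mb = np.stack([result.subject_maps[i][:, k] for i in ib])
            res = fwe_map_test(ma, mb, adj, n_perm=cfg.n_perm,
                               seed=sim_seeds[-1] + k,
                               E=cfg.tfce_E, H=cfg.tfce_H)
            for ch in range(ma.shape[1]):
                rows.append({"state": k + 1, "channel": ch + 1,
                             "t": res.t[ch], "p": res.p[ch],
                             "p_fwe": res.p_corrected[ch]})
        pd.DataFrame(rows).to_csv(outdir / "map_fwe.tsv", sep="\t", index=False)

    manifest = {
        "config": {f: getattr(cfg, f) for f in cfg.__dataclass_fields__},
        "sim_seeds": sim_seeds,
        "surrogate_null": surrogate_used,
        "n_subjects_total": len(result.groups),
        "hmm_score": float(result.params.score),
        "hmm_iterations": len(result.params.trace),
        "planted_to_decoded": result.planted_to_decoded.tolist(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("run complete -> %s", outdir)
    return outdir
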