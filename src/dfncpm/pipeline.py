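"""End-to-end pipeline: simulate/load -> windowed FC -> states -> mining
-> classification, with every intermediate artifact written to disk.

The run directory contains, per stage: the cohort manifest and ground
truth (when simulated), windowed-FC CSVs with JSON sidecars, centroid and
state-sequence CSVs, dwell statistics and group t-test tables, mined
pattern sets and the dichotomic partition as JSON, the one-hot feature
matrix as CSV, classification reports as JSON, a markdown summary and a
machine-readable run manifest (package version, seeds, config hash).
All stages are deterministic given the config seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._errors import ValidationError
from .classify import (
    ClassificationProtocol,
    dwell_feature_matrix,
    evaluate_classifiers,
    one_hot_encode,
)
from .dfnc import WindowSpec, estimate_windowed_fc
from .patterns import MiningSpec, dichotomic_split, mine_patterns
from .states import (
    assign_states,
    compare_groups_ttest,
    dwell_statistics,
    fit_states,
    select_k_elbow,
)
from .synthetic import SyntheticConfig, load_cohort, simulate_cohort, write_cohort

log = logging.getLogger("dfncpm")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one reproducible run needs.

    Either ``manifest`` points at an existing cohort or ``simulate`` is on
    and the synthetic config is used.  Defaults follow the study
    parameters throughout (26-TR window, sigma 3, k = 3, city-block
    k-means with 5 replicates, min support 0.05, 80/20 split, 100 x
    10-fold CV).
    """

    manifest: str | None = None
    simulate: bool = True
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    k: int = 3
    k_range: tuple = ()  # nonempty -> run elbow selection and use its k*
    distance: str = "cityblock"
    n_replicates: int = 5
    mining: MiningSpec = field(default_factory=MiningSpec)
    protocol: ClassificationProtocol = field(default_factory=ClassificationProtocol)
    dichotomy: tuple = ()  # (group_a, group_b); default: first two groups
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs:
            syn = dict(kwargs["synthetic"])
            if "groups" in syn:
                from .synthetic import GroupSpec

                syn["groups"] = tuple(
                    GroupSpec(g["label"], g["n_subjects"],
                              tuple(tuple(r) for r in g["transition_matrix"]))
                    for g in syn["groups"]
                )
            kwargs["synthetic"] = SyntheticConfig(**syn)
        if "window" in kwargs:
            kwargs["window"] = WindowSpec(**kwargs["window"])
        if "mining" in kwargs:
            kwargs["mining"] = MiningSpec(**kwargs["mining"])
        if "protocol" in kwargs:
            kwargs["protocol"] = ClassificationProtocol(**kwargs["protocol"])
        for key in ("k_range", "dichotomy"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=1, allow_nan=True))


def _stage(name):
    log.info("stage: %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the full analysis and return the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    timings = {}

    t0 = _stage("cohort")
    truth = None
    if config.simulate:
        cohort, truth = simulate_cohort(config.synthetic)
        write_cohort(cohort, truth, outdir / "cohort")
    else:
        if config.manifest is None:
            raise ValidationError("either simulate=True or a manifest is required")
        cohort = load_cohort(config.manifest)
    groups = {s.subject_id: s.group for s in cohort.subjects}
    timings["cohort"] = time.time() - t0

    t0 = _stage("dfnc")
    fc_dir = outdir / "dfnc"
    fc_dir.mkdir(exist_ok=True)
    series = []
    for i, subj in enumerate(cohort.subjects):
        try:
            s = estimate_windowed_fc(
                subj.data, config.window, subject_id=subj.subject_id,
                tr_seconds=subj.tr_seconds, seed=config.seed + i,
            )
        except Exception as exc:
            raise type(exc)(
                f"dfnc stage failed for subject {subj.subject_id!r}: {exc}"
            ) from exc
        series.append(s)
        np.savetxt(fc_dir / f"{subj.subject_id}_fc.csv", s.values, delimiter=",")
        _write_json(
            fc_dir / f"{subj.subject_id}_fc.json",
            {
                "subject_id": s.subject_id,
                "config_hash": cfg_hash,
                "window_starts": s.window_starts,
                "pairs": list(s.pairs),
                "estimator": s.estimator,
                "fisher_z": s.fisher_z,
                "lambda": s.lambda_,
            },
        )
    timings["dfnc"] = time.time() - t0

    t0 = _stage("states")
    pooled = np.vstack([s.values for s in series])
    k = config.k
    elbow = None
    if config.k_range:
        k_star, curve, low_conf = select_k_elbow(
            pooled, config.k_range, distance=config.distance,
            n_replicates=config.n_replicates, seed=config.seed,
        )
        elbow = {"k_star": k_star, "curve": list(curve), "low_confidence": low_conf}
        k = k_star
    model = fit_states(pooled, k=k, distance=config.distance,
                       n_replicates=config.n_replicates, seed=config.seed)
    state_dir = outdir / "states"
    state_dir.mkdir(exist_ok=True)
    np.savetxt(state_dir / "centroids.csv", model.centroids, delimiter=",")
    sequences = [assign_states(model, s) for s in series]
    rows = [
        (q.subject_id, int(w), int(lab))
        for q in sequences
        for w, lab in enumerate(q.labels)
    ]
    pd.DataFrame(rows, columns=["subject_id", "window_index", "state"]).to_csv(
        state_dir / "state_sequences.csv", index=False
    )
    dwell = {q.subject_id: dwell_statistics(q, k=k) for q in sequences}
    dwell_rows = []
    for sid, d in dwell.items():
        for s in range(1, k + 1):
            dwell_rows.append(
                (sid, groups[sid], s, d.fraction_time[s - 1],
                 d.mean_dwell_windows[s - 1], d.mean_dwell_seconds[s - 1])
            )
    dwell_df = pd.DataFrame(
        dwell_rows,
        columns=["subject_id", "group", "state", "fraction_time",
                 "mean_dwell_windows", "mean_dwell_seconds"],
    )
    dwell_df.to_csv(state_dir / "dwell_statistics.csv", index=False)
    timings["states"] = time.time() - t0

    group_labels = list(dict.fromkeys(groups.values()))
    if config.dichotomy:
        ga, gb = config.dichotomy
        if ga not in group_labels or gb not in group_labels:
            raise ValidationError(
                f"dichotomy {config.dichotomy} not present among groups "
                f"{group_labels}"
            )
    elif len(group_labels) >= 2:
        ga, gb = group_labels[0], group_labels[1]
    else:
        ga = gb = None

    ttest_rows = []
    if ga is not None:
        for s in range(1, k + 1):
            va = dwell_df.query("group == @ga and state == @s")["fraction_time"]
            vb = dwell_df.query("group == @gb and state == @s")["fraction_time"]
            res = compare_groups_ttest(va, vb)
            ttest_rows.append((s, res.t, res.p, res.df))
        ttests = pd.DataFrame(ttest_rows, columns=["state", "t", "p", "df"])
        # uncorrected p-values are primary; a Holm column is added for
        # transparency
        order = np.argsort(ttests["p"].to_numpy())
        m = len(ttests)
        holm = np.empty(m)
        prev = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * ttests["p"].iloc[idx])
            prev = max(prev, adj)
            holm[idx] = prev
        ttests["p_holm"] = holm
        ttests.to_csv(state_dir / "dwell_group_ttests.csv", index=False)

    t0 = _stage("mine")
    mine_dir = outdir / "patterns"
    mine_dir.mkdir(exist_ok=True)
    report_payload = {}
    if ga is not None:
        seqs_a = [q for q in sequences if groups[q.subject_id] == ga]
        seqs_b = [q for q in sequences if groups[q.subject_id] == gb]
        pat_a = mine_patterns(seqs_a, config.mining)
        pat_b = mine_patterns(seqs_b, config.mining)
        dpm = dichotomic_split(pat_a, pat_b)
        for label, pats in (("group_a", pat_a), ("group_b", pat_b)):
            _write_json(
                mine_dir / f"patterns_{label}.json",
                {
                    "group": ga if label == "group_a" else gb,
                    "config_hash": cfg_hash,
                    "n_sequences": pats.n_sequences,
                    "patterns": [
                        {"items": list(p), "support": s}
                        for p, s in pats.patterns.items()
                    ],
                },
            )
        _write_json(
            mine_dir / "dpm_result.json",
            {
                "config_hash": cfg_hash,
                "dichotomy": [ga, gb],
                "venn": dpm.summary(),
                "unique_a": [
                    {"items": list(p), "support_a": sa, "support_b": sb}
                    for p, (sa, sb) in dpm.unique_a.items()
                ],
                "unique_b": [
                    {"items": list(p), "support_a": sa, "support_b": sb}
                    for p, (sa, sb) in dpm.unique_b.items()
                ],
                "shared": [
                    {"items": list(p), "support_a": sa, "support_b": sb}
                    for p, (sa, sb) in dpm.shared.items()
                ],
            },
        )
        timings["mine"] = time.time() - t0

        t0 = _stage("classify")
        cls_dir = outdir / "classification"
        cls_dir.mkdir(exist_ok=True)
        in_dichotomy = [q for q in sequences if groups[q.subject_id] in (ga, gb)]
        feature_sets = {
            "dwell_times": dwell_feature_matrix(
                {q.subject_id: dwell[q.subject_id] for q in in_dichotomy},
                groups, k,
            ),
            "unique_a_patterns": one_hot_encode(
                in_dichotomy, dpm.unique_a, compress=config.mining.compress,
                n_states=k, groups=groups,
            ),
            "unique_b_patterns": one_hot_encode(
                in_dichotomy, dpm.unique_b, compress=config.mining.compress,
                n_states=k, groups=groups,
            ),
        }
        reports = {}
        for fam, feats in feature_sets.items():
            feats.to_frame().to_csv(cls_dir / f"features_{fam}.csv")
            if feats.values.shape[1] == 0:
                log.warning("feature family %s is empty; skipped", fam)
                continue
            reports[fam] = evaluate_classifiers(feats, config.protocol)
            _write_json(cls_dir / f"report_{fam}.json",
                        reports[fam].to_jsonable())
        report_payload = {
            fam: rep.to_jsonable() for fam, rep in reports.items()
        }
        timings["classify"] = time.time() - t0

    _write_json(
        outdir / "run_manifest.json",
        {
            "package": "dfncpm",
            "version": __version__,
            "config_hash": cfg_hash,
            "config": _jsonable(config),
            "elbow": elbow,
            "n_subjects": len(cohort.subjects),
            "groups": group_labels,
        },
    )
    summary = [f"# dfncpm run `{cfg_hash}`", ""]
    summary.append(f"- subjects: {len(cohort.subjects)} in groups {group_labels}")
    if sequences:
        summary.append(f"- windows per subject: {len(sequences[0].labels)}")
    summary.append(f"- states: k = {k}" + (f" (elbow over {list(config.k_range)})" if elbow else ""))
    if ga is not None:
        summary.append(
            f"- patterns ({ga} vs {gb}): {dpm.summary()['total']} total = "
            f"{len(dpm.unique_a)} unique to {ga} + {len(dpm.unique_b)} unique "
            f"to {gb} + {len(dpm.shared)} shared"
        )
        if report_payload:
            summary += ["", "## Classification (mean over repeated CV)", ""]
            summary.append(
                "| features | model | accuracy | AUC | recall | precision | F1 |"
            )
            summary.append("|---|---|---|---|---|---|---|")
            for fam, rep in report_payload.items():
                for mdl, met in rep["cv_metrics"].items():
                    cells = " | ".join(
                        f"{met[m]['mean']:.3f} ± {met[m]['sd']:.3f}"
                        for m in ("accuracy", "auc", "recall", "precision", "f1")
                    )
                    summary.append(f"| {fam} | {mdl.upper()} | {cells} |")
            summary += ["", "## Most discriminative patterns", ""]
            summary.append("| features | model | rank | pattern | importance |")
            summary.append("|---|---|---|---|---|")
            for fam, rep in report_payload.items():
                for mdl, ranks in rep["importances"].items():
                    for rank, item in enumerate(ranks, start=1):
                        summary.append(
                            f"| {fam} | {mdl.upper()} | {rank} | "
                            f"{item['feature']} | {item['importance']:.4f} |"
                        )
    (outdir / "summary.md").write_text("\n".join(summary) + "\n")
    log.info("timings: %s", {k: round(v, 2) for k, v in timings.items()})
    return outdir
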