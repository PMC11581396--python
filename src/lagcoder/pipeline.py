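"""Declarative experiment runner: config -> encoding results, partitions,
comparisons, provenance.

A session directory holds one ``eeg_run<k>.npz`` recording per run (with
JSON sidecars) plus per-model feature files ``<model>_run<k>.npz``, as
written by the ``lagcoder synth`` command or by user code via
:mod:`lagcoder.io`.  The config (YAML or dict) names models either as
feature-file patterns or as unions of other models, the lag range, the
penalty grid and the paired comparisons to run.  Outputs are tidy TSVs
plus a provenance record (config hash, seed, package version) that makes
any table regenerable; a model whose result file already carries the same
provenance hash is not recomputed (cheap resume after partial failure).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import union_features
from .containers import FeatureSeries
from .encoder import LagSpec, RidgeConfig, nested_cv
from .features import sliding_window_extract, resample_features
from .io import load_features, load_recording
from .stats import fdr_bh, signed_rank

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_experiment", "context_sweep",
           "plot_summaries"]

DEFAULT_CONTEXTS = (0.5, 1.0, 5.0, 10.0, 20.0, 30.0)


class AnalysisConfig:
    """Validated experiment configuration.

    Required keys: ``session`` (directory), ``models`` (mapping of name ->
    ``{"features": "<pattern with {run}>"}`` or ``{"union": [names]}``).
    Optional: ``lags`` ({min_lag_s, max_lag_s}), ``lambda_grid``,
    ``comparisons`` ([{a, b, tails}]), ``fdr_q``, ``seed``, ``out_dir``.
    """

    def __init__(self, cfg: dict, base_dir: Path | None = None):
        self.raw = dict(cfg)
        base = Path(base_dir) if base_dir else Path(".")
        self.session = (base / cfg["session"]).resolve()
        if not self.session.is_dir():
            raise ValueError(f"session directory {self.session} does not exist")
        self.models = dict(cfg["models"])
        for name, m in self.models.items():
            if "union" in m:
                undef = [p for p in m["union"] if p not in self.models]
                if undef:
                    raise ValueError(
                        f"model {name!r} references undefined model(s) {undef}")
            elif "features" not in m:
                raise ValueError(
                    f"model {name!r} needs a 'features' pattern or 'union' list")
        lags = cfg.get("lags", {})
        self.lags = LagSpec(lags.get("min_lag_s", 0.0),
                            lags.get("max_lag_s", 0.75),
                            lags.get("fs", 32.0))
        self.ridge = RidgeConfig(tuple(cfg.get(
            "lambda_grid", (0.1, 1.0, 1e1, 1e2, 1e3, 1e4, 1e5))))
        self.comparisons = list(cfg.get("comparisons", []))
        for comp in self.comparisons:
            for side in ("a", "b"):
                if comp[side] not in self.models:
                    raise ValueError(
                        f"comparison references undefined model {comp[side]!r}")
        self.fdr_q = float(cfg.get("fdr_q", 0.05))
        self.seed = int(cfg.get("seed", 0))
        self.out_dir = (base / cfg.get("out_dir", "results")).resolve()

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        path = Path(path)
        return cls(yaml.safe_load(path.read_text()), base_dir=path.parent)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _load_runs(session: Path):
    paths = sorted(session.glob("eeg_run*.npz"))
    if not paths:
        raise ValueError(f"no eeg_run*.npz recordings in {session}")
    return [load_recording(p) for p in paths]


def _model_features(cfg: AnalysisConfig, name: str, n_runs: int,
                    cache: dict) -> list:
    if name in cache:
        return cache[name]
    m = cfg.models[name]
    if "union" in m:
        parts = [_model_features(cfg, p, n_runs, cache) for p in m["union"]]
        runs = [union_features([part[r] for part in parts], name=name)
                for r in range(n_runs)]
    else:
        runs = []
        for r in range(n_runs):
            path = cfg.session / m["features"].format(run=r)
            if not path.with_suffix(".npz").exists():
                raise ValueError(f"model {name!r}: missing feature file {path}")
            runs.append(load_features(path))
    cache[name] = runs
    return runs


def run_experiment(cfg: AnalysisConfig | dict, force: bool = False) -> dict:
    """Run every configured model and comparison; returns a result bundle.

    Deterministic and idempotent for a fixed config: rerunning writes
    bit-identical tables.  Per-model TSVs carry (run, channel, r, lambda);
    a JSON summary holds scalp-average and per-channel Fisher-mean r.
    """
    if isinstance(cfg, dict):
        cfg = AnalysisConfig(cfg)
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    recs = _load_runs(cfg.session)
    runs_y = [r.data for r in recs]
    labels = recs[0].channel_labels
    n_runs = len(recs)
    cache: dict = {}
    provenance = {"config_hash": cfg.hash, "seed": cfg.seed,
                  "version": __version__}
    results = {}
    for name in cfg.models:
        table_path = out / f"encoding_{name}.tsv"
        summary_path = out / f"encoding_{name}.json"
        if not force and summary_path.exists():
            prev = json.loads(summary_path.read_text())
            if prev.get("provenance", {}).get("config_hash") == cfg.hash:
                logger.info("model %s: reusing checkpointed result", name)
                results[name] = prev
                continue
        try:
            feats = _model_features(cfg, name, n_runs, cache)
            res = nested_cv([f.data for f in feats], runs_y, cfg.lags, cfg.ridge)
        except Exception as exc:  # checkpointed partial failure
            raise RuntimeError(f"stage 'encode:{name}' failed: {exc}") from exc
        rows = [{"run": r, "channel": labels[c],
                 "r": res.per_run_r[r, c], "lambda": res.chosen_lambda[r]}
                for r in range(n_runs) for c in range(len(labels))]
        pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False,
                                  float_format="%.10g")
        summary = {
            "scalp_mean_r": res.scalp_mean_r,
            "mean_r": dict(zip(labels, res.mean_r.tolist())),
            "per_run_scalp_r": res.per_run_r.mean(axis=1).tolist(),
            "provenance": provenance,
        }
        summary_path.write_text(json.dumps(summary, indent=1))
        results[name] = summary
    comp_rows = []
    for comp in cfg.comparisons:
        a = np.asarray(results[comp["a"]]["per_run_scalp_r"])
        b = np.asarray(results[comp["b"]]["per_run_scalp_r"])
        st = signed_rank(a, b, tails=int(comp.get("tails", 2)),
                         method="auto")
        comp_rows.append({"a": comp["a"], "b": comp["b"], "tails": st.tails,
                          "z": st.statistic, "p": st.p, "n": st.n})
    if comp_rows:
        comp_df = pd.DataFrame(comp_rows)
        comp_df["p_fdr"] = fdr_bh(comp_df["p"].to_numpy(), cfg.fdr_q)[0]
        comp_df.to_csv(out / "comparisons.tsv", sep="\t", index=False,
                       float_format="%.10g")
        results["comparisons"] = comp_rows
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    return results


def context_sweep(extractor, waves: list, fs_audio: float, runs_y: list,
                  contexts=DEFAULT_CONTEXTS, layer: int = 0,
                  lags: LagSpec | None = None,
                  cfg: RidgeConfig | None = None,
                  window_s: float = 30.0) -> pd.DataFrame:
    """Accuracy per context-window restriction, plus pairwise tests.

    Re-extracts features per run with the sliding window restricted to each
    duration in ``contexts``, runs the full nested CV, and returns a tidy
    frame with one row per context (scalp-average accuracy and per-run
    scalp accuracies); pairwise signed-rank comparisons across runs between
    successive contexts are attached in ``DataFrame.attrs['pairwise']``.
    """
    lags = lags or LagSpec()
    n_target = np.asarray(runs_y[0]).shape[0]
    rows, per_ctx_runs = [], []
    for ctx in contexts:
        feats = []
        for w in waves:
            layers = sliding_window_extract(
                extractor, w, fs_audio, window_s=window_s,
                max_context_s=min(ctx, window_s))
            feats.append(resample_features(layers[layer], lags.fs,
                                           n_target=n_target).data)
        res = nested_cv(feats, runs_y, lags, cfg)
        run_means = res.per_run_r.mean(axis=1)
        per_ctx_runs.append(run_means)
        rows.append({"context_s": ctx, "scalp_mean_r": res.scalp_mean_r,
                     **{f"run{r}_r": v for r, v in enumerate(run_means)}})
    df = pd.DataFrame(rows)
    pairwise = []
    for i in range(1, len(contexts)):
        try:
            st = signed_rank(per_ctx_runs[i], per_ctx_runs[i - 1], tails=2,
                             method="auto")
            pairwise.append({"a": contexts[i], "b": contexts[i - 1],
                             "z": st.statistic, "p": st.p})
        except ValueError:  # identical accuracies (context-free extractor)
            pairwise.append({"a": contexts[i], "b": contexts[i - 1],
                             "z": 0.0, "p": 1.0})
    df.attrs["pairwise"] = pairwise
    return df


def plot_summaries(results: dict, out_dir, channel_positions=None) -> list:
    """Line plots of accuracy vs layer / context / lag; returns paths.

    ``results`` maps plot names to either a 1-D profile (lag or layer
    sweep) or a DataFrame from :func:`context_sweep`.  Empty input is a
    warned no-op.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not results:
        logger.warning("plot_summaries called with no results; nothing to do")
        return []
    paths = []
    for name, val in sorted(results.items()):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        if isinstance(val, pd.DataFrame):
            ax.plot(val.iloc[:, 0], val["scalp_mean_r"], "o-")
            ax.set_xlabel(val.columns[0])
        else:
            y = np.asarray(val, dtype=float).ravel()
            ax.plot(np.arange(y.size), y, "o-")
            ax.set_xlabel("index")
        ax.set_ylabel("prediction accuracy (r)")
        ax.set_title(name)
        fig.tight_layout()
        p = out_dir / f"{name}.svg"
        fig.savefig(p)
        plt.close(fig)
        paths.append(p)
    return paths
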