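"""End-to-end orchestration: simulate -> preprocess -> select -> train ->
evaluate -> decision-curve analysis, as a reproducible, logged run.

Every stage reads and writes plain-text artifacts under one output
directory, so any stage can be re-run in isolation, and a manifest
records the configuration, the derived per-stage seeds, SHA-256 hashes
of every artifact, library versions and timings.  Identical
configuration and master seed yield identical artifact hashes.

Seed derivation from the master seed (all taken mod 2^31):
cohort = seed, folds = seed + 1, forest = seed + 2, evaluation
bootstraps = seed + 3, decision-curve resampling = seed + 4.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decision_analysis import (
    CAP_DEFAULT,
    CapPrevalence,
    biopsy_net_reduction,
    decision_curves,
    default_threshold_grid,
)
from .evaluation import ENDPOINTS, auc_ci, auc_diff_pvalue, bca_mean_diff, prop_odds_or, roc_auc
from .feature_selection import FoldAssignment, SelectedFeatures, assign_folds
from .preprocess import VARIANTS, OmicsBlock, _read_matrix, read_cohort, write_cohort
from .risk_models import encode_outcome, preprocess_cohort, select_all, train_all
from .strata import GleasonStratum
from .synthetic import SyntheticSpec, default_spec, generate_cohort, planted_truth

log = logging.getLogger("exospec")

_MOD = 2**31


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    seed: int = 0
    outdir: str = "exospec_run"
    synthetic: SyntheticSpec | None = None  # None -> default study spec
    input_dir: str | None = None  # read an existing cohort instead of simulating
    k_folds: int = 20
    n_trees: int = 401
    subsample_fraction: float = 0.632
    b_auc: int = 1000
    b_bca: int = 1000
    b_dca: int = 1000
    n_out: int = 197
    cap: CapPrevalence = field(default_factory=lambda: CAP_DEFAULT)
    threshold_start: float = 0.05
    threshold_stop: float = 0.50
    threshold_step: float = 0.01

    def __post_init__(self) -> None:
        for name in ("k_folds", "n_trees", "b_auc", "b_bca", "b_dca", "n_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.threshold_start < self.threshold_stop < 1:
            raise ValueError("threshold grid must lie within (0, 1)")

    @property
    def thresholds(self) -> np.ndarray:
        return np.round(
            np.arange(self.threshold_start, self.threshold_stop + 1e-12, self.threshold_step),
            10,
        )

    def spec(self) -> SyntheticSpec:
        if self.synthetic is not None:
            return self.synthetic
        return default_spec(seed=self.seed % _MOD)

    # seed derivation -----------------------------------------------------
    @property
    def fold_seed(self) -> int:
        return (self.seed + 1) % _MOD

    @property
    def forest_seed(self) -> int:
        return (self.seed + 2) % _MOD

    @property
    def eval_seed(self) -> int:
        return (self.seed + 3) % _MOD

    @property
    def dca_seed(self) -> int:
        return (self.seed + 4) % _MOD

    # (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in ("synthetic", "cap")
        }
        d["synthetic"] = None if self.synthetic is None else self.synthetic.to_dict()
        d["cap"] = dataclasses.asdict(self.cap)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        kwargs = dict(data)
        if kwargs.get("synthetic") is not None:
            kwargs["synthetic"] = SyntheticSpec.from_dict(kwargs["synthetic"])
        if "cap" in kwargs and kwargs["cap"] is not None:
            kwargs["cap"] = CapPrevalence(**kwargs["cap"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _timed(stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            self.elapsed = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage=%s elapsed=%.2fs", stage, self.elapsed)
            return False

    return _Ctx()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig) -> Path:
    """Generate (or copy in) the cohort and write it under outdir/cohort."""
    out = Path(config.outdir) / "cohort"
    with _timed("simulate") as t:
        if config.input_dir is not None:
            patients, blocks = read_cohort(config.input_dir)
            sidecar = {"source": str(config.input_dir)}
        else:
            spec = config.spec()
            patients, clinical, peptide, evrna = generate_cohort(spec)
            blocks = {"clinical": clinical, "peptide": peptide, "evrna": evrna}
            sidecar = {"spec": spec.to_dict(), "planted_truth": planted_truth(spec)}
        write_cohort(out, patients, blocks, sidecar)
    log.info(
        "simulate: %d patients, %d peptides, %d probes",
        len(patients), blocks["peptide"].n_features, blocks["evrna"].n_features,
    )
    return out


def _load_cohort(config: RunConfig):
    return read_cohort(Path(config.outdir) / "cohort")


def stage_preprocess(config: RunConfig) -> Path:
    """Filter peptides, normalise EV-RNA, log-transform; write processed/."""
    out = Path(config.outdir) / "processed"
    with _timed("preprocess"):
        patients, blocks = _load_cohort(config)
        processed = preprocess_cohort(patients, blocks)
        write_cohort(out, patients, processed, sidecar={
            "scales": {k: b.scale for k, b in processed.items()},
            "n_features": {k: b.n_features for k, b in processed.items()},
        })
    log.info(
        "preprocess: peptide %d -> %d columns after detection filter",
        blocks["peptide"].n_features, processed["peptide"].n_features,
    )
    return out


def _load_processed(config: RunConfig):
    pdir = Path(config.outdir) / "processed"
    patients, _ = read_cohort(Path(config.outdir) / "cohort")
    ids = patients["id"].to_numpy()
    blocks = {
        "clinical": _read_matrix(pdir / "clinical.tsv", ids, "clinical", "raw"),
        "peptide": _read_matrix(pdir / "peptide.tsv", ids, "peptide", "log2"),
        "evrna": _read_matrix(pdir / "evrna.tsv", ids, "evrna", "log2"),
    }
    return patients, blocks


def stage_select(config: RunConfig) -> Path:
    """CV-LASSO selection for every variant; writes selection.json."""
    out = Path(config.outdir) / "selection.json"
    with _timed("select"):
        patients, blocks = _load_processed(config)
        y = np.array([encode_outcome(s) for s in patients["stratum"]])
        folds = assign_folds(len(y), k=config.k_folds, seed=config.fold_seed)
        selections = select_all(blocks, y, folds)
        out.write_text(json.dumps(
            {v: sel.to_dict() for v, sel in selections.items()}, indent=2, sort_keys=True
        ))
    for v, sel in selections.items():
        log.info("select: %s -> %d features (alpha=%.4g)", v, len(sel.names), sel.alpha)
    return out


def _load_selections(config: RunConfig, folds: FoldAssignment) -> dict[str, SelectedFeatures]:
    data = json.loads((Path(config.outdir) / "selection.json").read_text())
    out = {}
    for variant, d in data.items():
        names = list(d["features"])
        coefs = np.array([d["features"][n] for n in names])
        out[variant] = SelectedFeatures(variant, names, coefs, d["alpha"], folds)
    return out


def stage_train(config: RunConfig) -> Path:
    """Fit the four forests on their selections; writes risk_scores.tsv."""
    out = Path(config.outdir) / "risk_scores.tsv"
    with _timed("train"):
        patients, blocks = _load_processed(config)
        y = np.array([encode_outcome(s) for s in patients["stratum"]])
        folds = assign_folds(len(y), k=config.k_folds, seed=config.fold_seed)
        selections = _load_selections(config, folds)
        scores, _ = train_all(
            blocks, patients, y, selections,
            n_trees=config.n_trees,
            subsample_fraction=config.subsample_fraction,
            forest_seed=config.forest_seed,
        )
        rows = []
        for variant in VARIANTS:
            rs = scores[variant]
            for pid, score, stratum in zip(patients["id"], rs.scores, patients["stratum"]):
                rows.append((pid, variant, f"{score:.10f}", stratum.value))
        pd.DataFrame(rows, columns=["id", "variant", "score", "stratum"]).to_csv(
            out, sep="\t", index=False
        )
    log.info("train: %d trees x %d variants, OOB scores written", config.n_trees, len(VARIANTS))
    return out


def _load_scores(config: RunConfig):
    patients, _ = _load_cohort(config)
    df = pd.read_csv(Path(config.outdir) / "risk_scores.tsv", sep="\t", dtype={"id": str})
    scores = {}
    for variant in VARIANTS:
        sub = df[df["variant"] == variant].set_index("id").loc[patients["id"]]
        scores[variant] = sub["score"].to_numpy(float)
    return patients, scores


def stage_evaluate(config: RunConfig) -> Path:
    """AUCs with stratified-bootstrap CIs, pairwise p-values vs the
    integrated model, proportional-odds OR, and BCa mean differences."""
    out = Path(config.outdir) / "evaluation.json"
    with _timed("evaluate"):
        patients, scores = _load_scores(config)
        strata = list(patients["stratum"])
        report: dict = {"auc": {}, "proportional_odds": {}, "estimation": {}}
        for ep_name, endpoint in ENDPOINTS.items():
            report["auc"][ep_name] = {}
            for variant in VARIANTS:
                ci = auc_ci(
                    scores[variant], endpoint, strata,
                    B=config.b_auc, seed=config.eval_seed,
                )
                entry = {
                    "auc": round(ci.point, 4),
                    "ci": [round(ci.lower, 4), round(ci.upper, 4)],
                }
                if variant != "ExoSpec":
                    entry["p_exospec_greater"] = auc_diff_pvalue(
                        scores["ExoSpec"], scores[variant], endpoint, strata,
                        B=config.b_auc, seed=config.eval_seed,
                    )
                report["auc"][ep_name][variant] = entry
        orr = prop_odds_or(scores["ExoSpec"], strata)
        report["proportional_odds"]["ExoSpec"] = {
            "or_per_0.1": round(orr.point, 3),
            "ci": [round(orr.lower, 3), round(orr.upper, 3)],
        }
        nec = scores["ExoSpec"][[s is GleasonStratum.NEC for s in strata]]
        groups = {
            "neg_biopsy": [GleasonStratum.NEG_BIOPSY],
            "gs3_3": [GleasonStratum.GS3_3],
            "gs3_4": [GleasonStratum.GS3_4],
            "ge_4_3": [GleasonStratum.GS4_3, GleasonStratum.GS4PLUS],
        }
        for name, members in groups.items():
            grp = scores["ExoSpec"][[s in members for s in strata]]
            est = bca_mean_diff(nec, grp, B=config.b_bca, seed=config.eval_seed)
            report["estimation"][f"{name}_minus_nec"] = {
                "mean_diff": round(est.point, 4),
                "ci": [round(est.lower, 4), round(est.upper, 4)],
            }
        out.write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("evaluate: %d endpoints x %d variants", len(ENDPOINTS), len(VARIANTS))
    return out


def stage_dca(config: RunConfig) -> tuple[Path, Path]:
    """Decision curves and biopsy net reduction on CAP-matched resamples."""
    curves_path = Path(config.outdir) / "decision_curves.tsv"
    red_path = Path(config.outdir) / "biopsy_reduction.tsv"
    with _timed("dca"):
        patients, scores = _load_scores(config)
        strata = list(patients["stratum"])
        psa = patients["psa"].to_numpy(float)
        curve_rows, red_rows = [], []
        for ep_name, endpoint in ENDPOINTS.items():
            dc = decision_curves(
                scores, strata, psa, endpoint,
                thresholds=config.thresholds, cap=config.cap,
                n_out=config.n_out, B=config.b_dca, seed=config.dca_seed,
            )
            for j, t in enumerate(dc.thresholds):
                for model in VARIANTS:
                    curve_rows.append(
                        (ep_name, f"{t:.2f}", model, f"{dc.model_snb[model][j]:.6f}")
                    )
                curve_rows.append((ep_name, f"{t:.2f}", "treat_all", f"{dc.treat_all_snb[j]:.6f}"))
                curve_rows.append((ep_name, f"{t:.2f}", "treat_none", "0.000000"))
                for model in VARIANTS:
                    if model == "SoC":
                        continue
                    red = biopsy_net_reduction(
                        dc.model_nb[model][j], dc.model_nb["SoC"][j], float(t)
                    )
                    red_rows.append((ep_name, f"{t:.2f}", model, f"{red:.4f}"))
        pd.DataFrame(
            curve_rows, columns=["endpoint", "threshold", "model", "mean_snb"]
        ).to_csv(curves_path, sep="\t", index=False)
        pd.DataFrame(
            red_rows, columns=["endpoint", "threshold", "model", "reduction_per_100"]
        ).to_csv(red_path, sep="\t", index=False)
    log.info("dca: %d resamples of %d, %d thresholds", config.b_dca, config.n_out,
             len(config.thresholds))
    return curves_path, red_path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: RunConfig) -> dict:
    """Run every stage and write a manifest; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [
        ("simulate", stage_simulate),
        ("preprocess", stage_preprocess),
        ("select", stage_select),
        ("train", stage_train),
        ("evaluate", stage_evaluate),
        ("dca", stage_dca),
    ]
    timings = {}
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            fn(config)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)

    import scipy
    import sklearn
    import statsmodels

    artifacts = sorted(
        p for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": config.to_dict(),
        "seeds": {
            "master": config.seed,
            "folds": config.fold_seed,
            "forest": config.forest_seed,
            "evaluation": config.eval_seed,
            "dca": config.dca_seed,
        },
        "versions": {
            "exospec": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "artifacts": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
        "timings_s": timings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete: %d artifacts under %s", len(artifacts), outdir)
    return manifest
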