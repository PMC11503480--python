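"""Stage II: regression refinement of the marker-based estimates.

Two independent regressors — one for completeness, one for
contamination, each with its own count-ratio-histogram resolution
(defaults c_max = 6 and 12) — are trained on mean-CRH feature vectors of
simulated bins with known ground truth, with the stage-I estimates
appended as extra features.  The default model is a one-hidden-layer
MLP with 100 units; K-nearest-neighbor, random-forest, linear-SVR and
elastic-net regressors are registered alternates.  Features are
standardized inside the model pipeline (training statistics only), and
all methods are deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from sklearn.linear_model import ElasticNetCV
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVR

from .crh import build_features, feature_names, mean_crh
from .profiles import DomainProfile
from .reference_db import ReferenceDatabase
from .stage1 import (
    DEFAULT_K,
    ROUTE_REFINE,
    ROUTE_REJECTED,
    Stage1Result,
    run_stage1,
)

METHODS = ("mlp", "knn", "random_forest", "linear_svr", "elastic_net")
MIN_TRAINING_SAMPLES = 20


class TrainingError(ValueError):
    pass


class LeakageError(ValueError):
    """Train and validation sets share source genomes."""


class ModelSchemaError(ValueError):
    """Persisted model does not match the requested configuration."""


@dataclass
class Stage2Config:
    """Hyperparameters of the stage-II refinement.

    Defaults are the selected operating point: MLP with 100 hidden
    units, K = 9 stage-I neighbors, c_max = 6 for completeness and 12
    for contamination, weight decay 1e-4 / 1e-7 respectively.
    """

    method: str = "mlp"
    K: int = DEFAULT_K
    c_max_comp: int = 6
    c_max_cont: int = 12
    alpha_comp: float = 1e-4
    alpha_cont: float = 1e-7
    hidden_units: int = 100
    svr_C: float = 1.0
    knn_k: int = 10
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-6
    cont_ceiling: float = 1.0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; registered: {METHODS}"
            )


@dataclass
class QueryBin:
    """A (simulated or real) bin reduced to its profile and ground truth."""

    bin_id: str
    profile: DomainProfile
    truth_completeness: Optional[float] = None
    truth_contamination: Optional[float] = None
    source_genome: Optional[str] = None


@dataclass
class QualityModel:
    """The trained pair of regressors plus their feature schemas."""

    comp_model: Pipeline
    cont_model: Pipeline
    config: Stage2Config
    feature_schema_comp: List[str]
    feature_schema_cont: List[str]
    training_fingerprint: str = ""


@dataclass
class Prediction:
    """Final pipeline output for one query."""

    bin_id: str
    completeness: float
    contamination: float
    stage_used: str  # 'stage1', 'stage2' or 'rejected'
    stage1: Stage1Result
    reject_reason: Optional[str] = None


# ---------------------------------------------------------------------------
# Regressor registry and training
# ---------------------------------------------------------------------------

def _make_regressor(config: Stage2Config, target_kind: str):
    alpha = config.alpha_comp if target_kind == "completeness" else config.alpha_cont
    if config.method == "mlp":
        # Full-batch quasi-Newton: converges reliably at the training-set
        # sizes this package targets, where SGD-style solvers stall.
        return MLPRegressor(
            hidden_layer_sizes=(config.hidden_units,),
            alpha=alpha,
            solver="lbfgs",
            max_iter=config.max_iter,
            tol=config.tol,
            random_state=config.seed,
        )
    if config.method == "knn":
        return KNeighborsRegressor(n_neighbors=config.knn_k)
    if config.method == "random_forest":
        return RandomForestRegressor(random_state=config.seed)
    if config.method == "linear_svr":
        return LinearSVR(C=config.svr_C, random_state=config.seed, max_iter=10_000)
    if config.method == "elastic_net":
        return ElasticNetCV(random_state=config.seed)
    raise ValueError(f"unknown method {config.method!r}")


def train_model(
    features: np.ndarray,
    targets: np.ndarray,
    config: Stage2Config,
    target_kind: str,
) -> Pipeline:
    """Fit one standardize-then-regress pipeline for one quality index."""
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if target_kind not in ("completeness", "contamination"):
        raise ValueError(f"unknown target kind {target_kind!r}")
    if features.ndim != 2 or features.shape[0] != targets.shape[0]:
        raise TrainingError("features and targets must align row-wise")
    if features.shape[0] < MIN_TRAINING_SAMPLES:
        raise TrainingError(
            f"need >= {MIN_TRAINING_SAMPLES} training bins, got {features.shape[0]}"
        )
    if not (np.isfinite(features).all() and np.isfinite(targets).all()):
        raise TrainingError("NaN or infinite values in training data")
    pipe = Pipeline(
        [("scale", StandardScaler()), ("reg", _make_regressor(config, target_kind))]
    )
    pipe.fit(features, targets)
    return pipe


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def featurize(
    profile: DomainProfile, db: ReferenceDatabase, config: Stage2Config
) -> Tuple[Stage1Result, Optional[np.ndarray], Optional[np.ndarray]]:
    """Stage-I result plus the two stage-II feature vectors.

    Feature vectors are None when the query is rejected (prefilter or
    empty marker set); rejected bins carry no usable estimates.
    """
    s1 = run_stage1(profile, db, config.K)
    if s1.route == ROUTE_REJECTED:
        return s1, None, None
    neighbor_profiles = [db.get(gid).profile for gid, _ in s1.neighbor_ids]
    feats = []
    for c_max in (config.c_max_comp, config.c_max_cont):
        crh = mean_crh(profile, neighbor_profiles, c_max)
        feats.append(build_features(crh, s1).as_vector())
    return s1, feats[0], feats[1]


def _featurize_bins(
    bins: Sequence[QueryBin], db: ReferenceDatabase, config: Stage2Config
):
    rows_comp, rows_cont, targets_comp, targets_cont, kept = [], [], [], [], []
    for b in bins:
        s1, fc, fk = featurize(b.profile, db, config)
        if fc is None:
            continue
        rows_comp.append(fc)
        rows_cont.append(fk)
        targets_comp.append(b.truth_completeness)
        targets_cont.append(b.truth_contamination)
        kept.append(b)
    return (
        np.array(rows_comp),
        np.array(rows_cont),
        np.array(targets_comp, dtype=float),
        np.array(targets_cont, dtype=float),
        kept,
    )


def _fingerprint(config: Stage2Config, *arrays: np.ndarray) -> str:
    h = hashlib.sha256(json.dumps(asdict(config), sort_keys=True).encode())
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def train_quality_model(
    train_bins: Sequence[QueryBin],
    db: ReferenceDatabase,
    config: Optional[Stage2Config] = None,
) -> QualityModel:
    """Featurize training bins and fit both per-index regressors."""
    config = config or Stage2Config()
    Xc, Xk, yc, yk, kept = _featurize_bins(train_bins, db, config)
    if len(kept) < MIN_TRAINING_SAMPLES:
        raise TrainingError(
            f"only {len(kept)} of {len(train_bins)} training bins were usable"
        )
    comp_model = train_model(Xc, yc, config, "completeness")
    cont_model = train_model(Xk, yk, config, "contamination")
    return QualityModel(
        comp_model=comp_model,
        cont_model=cont_model,
        config=config,
        feature_schema_comp=feature_names(config.c_max_comp),
        feature_schema_cont=feature_names(config.c_max_cont),
        training_fingerprint=_fingerprint(config, Xc, yc, Xk, yk),
    )


# ---------------------------------------------------------------------------
# Full-pipeline prediction
# ---------------------------------------------------------------------------

def predict_quality(
    profile: DomainProfile,
    db: ReferenceDatabase,
    model: Optional[QualityModel] = None,
    config: Optional[Stage2Config] = None,
    bin_id: Optional[str] = None,
) -> Prediction:
    """Prefilter -> KNN -> markers -> stage I -> route -> (stage II).

    Without a trained model every non-rejected query reports stage I.
    Stage-II outputs are clipped to completeness in [0, 1] and
    contamination in [0, cont_ceiling].
    """
    config = config or (model.config if model else Stage2Config())
    bin_id = bin_id or profile.genome_id
    s1, feat_comp, feat_cont = featurize(profile, db, config)
    if s1.route == ROUTE_REJECTED:
        return Prediction(
            bin_id=bin_id,
            completeness=float("nan"),
            contamination=float("nan"),
            stage_used="rejected",
            stage1=s1,
            reject_reason=s1.reject_reason,
        )
    if s1.route == ROUTE_REFINE and model is not None:
        comp = float(model.comp_model.predict(feat_comp.reshape(1, -1))[0])
        cont = float(model.cont_model.predict(feat_cont.reshape(1, -1))[0])
        return Prediction(
            bin_id=bin_id,
            completeness=float(np.clip(comp, 0.0, 1.0)),
            contamination=float(np.clip(cont, 0.0, config.cont_ceiling)),
            stage_used="stage2",
            stage1=s1,
        )
    return Prediction(
        bin_id=bin_id,
        completeness=s1.completeness_clamped,
        contamination=s1.contamination,
        stage_used="stage1",
        stage1=s1,
    )


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def _check_disjoint(train_bins, valid_bins) -> None:
    t = {b.source_genome for b in train_bins if b.source_genome}
    v = {b.source_genome for b in valid_bins if b.source_genome}
    overlap = t & v
    if overlap:
        raise LeakageError(
            f"train and validation bins share source genomes: {sorted(overlap)[:5]}"
        )


def grid_search(
    train_bins: Sequence[QueryBin],
    valid_bins: Sequence[QueryBin],
    db: ReferenceDatabase,
    grid: Dict[str, List],
    base_config: Optional[Stage2Config] = None,
) -> Tuple[Stage2Config, List[Dict]]:
    """Exhaustive search over the cartesian hyperparameter grid.

    ``grid`` maps Stage2Config field names to candidate value lists.
    Every combination is trained on ``train_bins`` and scored by
    validation MAE (mean of the completeness and contamination MAEs, in
    percentage points).  Returns the argmin config and the full score
    table, deterministic given the config seed.
    """
    _check_disjoint(train_bins, valid_bins)
    base = base_config or Stage2Config()
    valid_fields = set(asdict(base))
    for key in grid:
        if key not in valid_fields:
            raise ValueError(f"unknown hyperparameter {key!r}")
    if "method" in grid:
        for m in grid["method"]:
            if m not in METHODS:
                raise ValueError(f"method {m!r} not in registry {METHODS}")

    keys = sorted(grid)
    table: List[Dict] = []
    best: Tuple[float, int] = (float("inf"), -1)
    configs: List[Stage2Config] = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        config = replace(base, **dict(zip(keys, combo)))
        model = train_quality_model(train_bins, db, config)
        errs_c, errs_k = [], []
        for b in valid_bins:
            pred = predict_quality(b.profile, db, model, config, b.bin_id)
            if pred.stage_used == "rejected":
                continue
            errs_c.append(abs(pred.completeness - b.truth_completeness))
            errs_k.append(abs(pred.contamination - b.truth_contamination))
        if errs_c:
            mae_c = 100.0 * float(np.mean(errs_c))
            mae_k = 100.0 * float(np.mean(errs_k))
            score = (mae_c + mae_k) / 2.0
        else:  # every validation bin rejected under this config
            mae_c = mae_k = score = float("inf")
        table.append(
            {**dict(zip(keys, combo)), "mae_completeness": mae_c,
             "mae_contamination": mae_k, "score": score}
        )
        configs.append(config)
        if score < best[0]:
            best = (score, len(configs) - 1)
    return configs[best[1]], table


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: QualityModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "config.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "config": asdict(model.config),
                "feature_schema_comp": model.feature_schema_comp,
                "feature_schema_cont": model.feature_schema_cont,
                "training_fingerprint": model.training_fingerprint,
            },
            fh,
            indent=2,
        )
    joblib.dump(model.comp_model, d / "comp_model.joblib")
    joblib.dump(model.cont_model, d / "cont_model.joblib")


def load_model(directory) -> QualityModel:
    d = Path(directory)
    try:
        with open(d / "config.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        comp_model = joblib.load(d / "comp_model.joblib")
        cont_model = joblib.load(d / "cont_model.joblib")
    except (OSError, json.JSONDecodeError, EOFError) as exc:
        raise IOError(f"cannot load model from {d}: {exc}") from exc
    config = Stage2Config(**meta["config"])
    for schema_key, c_max in (
        ("feature_schema_comp", config.c_max_comp),
        ("feature_schema_cont", config.c_max_cont),
    ):
        if meta[schema_key] != feature_names(c_max):
            raise ModelSchemaError(
                f"{schema_key} does not match c_max={c_max} of the stored config"
            )
    return QualityModel(
        comp_model=comp_model,
        cont_model=cont_model,
        config=config,
        feature_schema_comp=meta["feature_schema_comp"],
        feature_schema_cont=meta["feature_schema_cont"],
        training_fingerprint=meta.get("training_fingerprint", ""),
    )
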