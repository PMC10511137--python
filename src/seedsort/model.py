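"""Sparse PLS-DA discriminant models for seed-quality scoring.

Derivation chain for each preprocessing variant:

1. fit an ordinary PLS-DA model (PLS regression on the +-1 eligibility
   dummy; the continuous prediction is the discriminant score);
2. compute its standardized partial regression coefficients (SPRCs)
   ``beta_j = coef_j * sd(x_j) / sd(y)``;
3. run an adaptive LASSO with per-waveband penalty weight
   ``1 / |beta_j|`` (wavebands with zero SPRC are hard-excluded) and
   collect the distinct supports along the regularization path;
4. refit PLS-DA on each support; evaluate every candidate by mutual
   outer cross-validation over the paired duplicate captures (train on
   one capture of the trays, score the other, and vice versa).

Candidates are ranked by standard-condition precision ``sP`` with
AUC-rPR as tie-break, optionally aggregated over repeated resampled
fold assignments.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from .errors import (
    DegenerateDataError,
    InputError,
    PreprocessMismatchError,
)
from .metrics import ScoredBatch, StandardSummary, standard_summary
from .preprocess import PreprocessSpec, SpectraMatrix

logger = logging.getLogger(__name__)

SERIALIZATION_VERSION = 1


@dataclass
class LabeledDataset:
    """Per-seed spectra with eligibility labels and capture provenance."""

    spectra: SpectraMatrix
    y: np.ndarray
    seed_ids: np.ndarray
    capture_id: np.ndarray
    planted_bands: np.ndarray | None = None  # synthetic-data ground truth

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y).ravel().astype(int)
        self.seed_ids = np.asarray(self.seed_ids).ravel()
        self.capture_id = np.asarray(self.capture_id).ravel().astype(int)
        n = self.spectra.n_seeds
        if not (self.y.size == self.seed_ids.size == self.capture_id.size == n):
            raise InputError("rows of X, y, seed_ids and capture_id must align")
        if not np.all(np.isin(self.y, (-1, 1))):
            raise InputError("labels must be +1 or -1")
        # each seed at most once per capture
        pairs = set()
        for sid, cap in zip(self.seed_ids.tolist(), self.capture_id.tolist()):
            if (sid, cap) in pairs:
                raise InputError(f"seed {sid} appears twice in capture {cap}")
            pairs.add((sid, cap))

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class PLSDAModel:
    """Fitted (possibly sparse) PLS-DA discriminant.

    ``support`` indexes the wavebands of the training variant matrix;
    ``coefficients`` are raw regression coefficients on the support so
    that ``score = X[:, support] @ coefficients + intercept``.
    ``sprc``/``vip`` are per-support-waveband diagnostics.
    """

    n_components: int
    support: np.ndarray
    wavelengths: np.ndarray  # nm, of the support
    coefficients: np.ndarray
    intercept: float
    sprc: np.ndarray
    vip: np.ndarray
    preprocess: PreprocessSpec | None = None
    meta: dict = field(default_factory=dict)
    # per-component arrays kept for VIP recomputation / inspection
    x_weights: np.ndarray | None = None
    y_ss: np.ndarray | None = None

    @property
    def n_wavebands(self) -> int:
        return int(self.support.size)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Discriminant scores for a matrix over the *full* waveband axis."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X[:, self.support] @ self.coefficients + self.intercept


def _check_two_classes(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise DegenerateDataError("all seeds carry the same label")
    if min((y == 1).sum(), (y == -1).sum()) < 2:
        raise DegenerateDataError("need at least 2 seeds per class")


def _cv_mse(X, y, a, cv, rng) -> float:
    kf = KFold(n_splits=cv, shuffle=True, random_state=rng)
    err = 0.0
    for tr, te in kf.split(X):
        pls = PLSRegression(n_components=a, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(X[tr], y[tr])
        pred = pls.predict(X[te]).ravel()
        err += np.sum((pred - y[te]) ** 2)
    return err / len(y)


def select_n_components(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 20,
    cv: int = 10,
    random_state=None,
    patience: int | None = None,
) -> int:
    """Latent-variable count minimizing K-fold cross-validated MSE.

    With ``patience`` set, the scan over component counts stops after
    that many consecutive increases of the CV MSE past the running
    minimum (the MSE curve is near-convex in practice).
    """
    n, p = X.shape
    cap = int(min(max_components, p, n - 1 - n // cv))
    if cap < 1:
        raise DegenerateDataError("too few samples to cross-validate")
    seed = int(np.random.default_rng(random_state).integers(2**31 - 1))
    best_a, best_mse, worse = 1, np.inf, 0
    for a in range(1, cap + 1):
        mse = _cv_mse(X, y, a, cv, seed)
        if mse < best_mse:
            best_a, best_mse, worse = a, mse, 0
        else:
            worse += 1
            if patience is not None and worse >= patience:
                break
    return best_a


def fit_plsda(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | str = "auto",
    max_components: int = 20,
    cv: int = 10,
    wavelengths: np.ndarray | None = None,
    preprocess: PreprocessSpec | None = None,
    support: np.ndarray | None = None,
    random_state=None,
) -> PLSDAModel:
    """Fit a PLS-DA discriminant on (a support of) the waveband axis.

    X is column-centered by the fit (no column scaling by default; the
    +-1 dummy is the regression target).  With ``n_components="auto"``
    the latent-variable count minimizes K-fold cross-validated MSE.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise InputError("X rows and y must align")
    _check_two_classes(y.astype(int))
    p_full = X.shape[1]
    if support is None:
        support = np.arange(p_full)
    else:
        support = np.asarray(support, dtype=int)
    Xs = X[:, support]

    if n_components == "auto":
        a = select_n_components(
            Xs, y, max_components=max_components, cv=cv, random_state=random_state
        )
    else:
        a = int(n_components)
        if not 1 <= a <= min(Xs.shape):
            raise InputError(f"n_components={a} out of range for shape {Xs.shape}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=a, scale=False)
        pls.fit(Xs, y)

    coef = np.asarray(pls.coef_).reshape(-1)
    # sklearn predicts on centered X; fold the centering into the intercept
    intercept = float(y.mean() - Xs.mean(axis=0) @ coef)

    # SPRC: coefficient rescaled by column sd / response sd
    sd_x = Xs.std(axis=0)
    sd_y = y.std()
    zero_var = sd_x == 0
    if zero_var.any():
        logger.warning(
            "%d zero-variance waveband(s): SPRC undefined, set to 0",
            int(zero_var.sum()),
        )
    sprc = np.where(zero_var, 0.0, coef * sd_x / sd_y)

    # y-variance sum of squares per component for VIP
    T = pls.x_scores_
    q = pls.y_loadings_.reshape(-1)
    y_ss = (q**2) * np.sum(T**2, axis=0)

    model = PLSDAModel(
        n_components=a,
        support=support,
        wavelengths=(
            np.asarray(wavelengths, dtype=float)[support]
            if wavelengths is not None
            else support.astype(float)
        ),
        coefficients=coef,
        intercept=intercept,
        sprc=sprc,
        vip=np.empty(0),
        preprocess=preprocess,
        x_weights=pls.x_weights_,
        y_ss=y_ss,
    )
    model.vip = compute_vip(model)
    return model


def compute_sprc(model: PLSDAModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Standardized partial regression coefficients on the model support."""
    X = np.atleast_2d(np.asarray(X, dtype=float))[:, model.support]
    y = np.asarray(y, dtype=float).ravel()
    sd_x = X.std(axis=0)
    sd_y = y.std()
    if sd_y == 0:
        raise DegenerateDataError("response has zero variance")
    return np.where(sd_x == 0, 0.0, model.coefficients * sd_x / sd_y)


def compute_vip(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection over the model's support.

    ``VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )``
    with ``SS_a`` the y-variance captured by component ``a``; the mean
    of squared VIP over the support is 1 by construction.
    """
    if model.x_weights is None or model.y_ss is None:
        raise InputError("model lacks stored per-component arrays")
    W = model.x_weights  # (p, a)
    p = W.shape[0]
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    num = (wn**2) @ model.y_ss
    return np.sqrt(p * num / model.y_ss.sum())


# ---------------------------------------------------------------------------
# Adaptive LASSO


@dataclass
class AdaptiveLassoPath:
    """Solution path of the SPRC-weighted adaptive LASSO."""

    alphas: np.ndarray
    coefficients: np.ndarray  # (p_full, n_alphas), back-scaled
    supports: list  # distinct non-empty supports, ordered by size
    excluded: np.ndarray  # wavebands with zero SPRC (infinite penalty)


def adaptive_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    n_alphas: int = 100,
    eps: float = 1e-4,
    tol: float = 1e-4,
) -> AdaptiveLassoPath:
    """L1 path with per-waveband penalty weights ``1/|beta_j]``.

    Realized by rescaling column ``j`` by ``|beta_j|``, running a
    standard lasso path over a decreasing geometric alpha grid from the
    smallest alpha with empty support, then back-scaling coefficients.
    Wavebands with ``beta_j = 0`` never enter (infinite penalty).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.size != X.shape[1]:
        raise InputError("one SPRC per waveband required")
    if np.all(beta == 0):
        raise DegenerateDataError("all SPRCs are zero; nothing to weight")
    keep = np.flatnonzero(beta != 0)
    Xw = X[:, keep] * np.abs(beta[keep])
    Xc = Xw - Xw.mean(axis=0)
    yc = y - y.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alphas, coefs_w, _ = lasso_path(
            Xc, yc, n_alphas=n_alphas, eps=eps, tol=tol, max_iter=5000
        )
    coefs = np.zeros((X.shape[1], alphas.size))
    coefs[keep, :] = coefs_w * np.abs(beta[keep])[:, None]

    supports, seen = [], set()
    for i in range(alphas.size):
        sup = tuple(np.flatnonzero(coefs[:, i] != 0).tolist())
        if sup and sup not in seen:
            seen.add(sup)
            supports.append(np.array(sup, dtype=int))
    supports.sort(key=lambda s: (s.size, tuple(s)))
    return AdaptiveLassoPath(
        alphas=alphas,
        coefficients=coefs,
        supports=supports,
        excluded=np.flatnonzero(beta == 0),
    )


# ---------------------------------------------------------------------------
# Candidate derivation and ranking


@dataclass
class Candidate:
    """One refit model plus its outer-cross-validated performance."""

    model: PLSDAModel
    summary: StandardSummary
    variant_index: int
    support_size: int
    is_sparse: bool


@dataclass
class CandidateSet:
    """Candidates from all variants, with data refs for re-ranking."""

    candidates: list
    ranking: np.ndarray
    dataset: LabeledDataset | None = None
    variants: dict | None = None

    def top(self) -> Candidate:
        return self.candidates[int(self.ranking[0])]

    def top_sparse(self) -> Candidate:
        for idx in self.ranking:
            if self.candidates[int(idx)].is_sparse:
                return self.candidates[int(idx)]
        raise InputError("no sparse candidate present")


def _capture_folds(dataset: LabeledDataset, rng=None):
    """Mutual outer cross-validation folds.

    With paired duplicate captures (trays imaged twice): train on one
    capture, score the other, and vice versa, so a seed is never scored
    by a model trained on the same capture of that seed.  Falls back to
    seeded seed-level 2-fold CV, with a warning, when only one capture
    exists.
    """
    caps = np.unique(dataset.capture_id)
    if caps.size >= 2:
        half = caps[: caps.size // 2 or 1]
        in_first = np.isin(dataset.capture_id, half)
        return [
            (np.flatnonzero(in_first), np.flatnonzero(~in_first)),
            (np.flatnonzero(~in_first), np.flatnonzero(in_first)),
        ]
    logger.warning("single capture: falling back to seed-level 2-fold CV")
    rng = np.random.default_rng(rng)
    seeds = np.unique(dataset.seed_ids)
    mask = np.zeros(seeds.size, dtype=bool)
    mask[rng.permutation(seeds.size)[: seeds.size // 2]] = True
    first = np.isin(dataset.seed_ids, seeds[mask])
    return [
        (np.flatnonzero(first), np.flatnonzero(~first)),
        (np.flatnonzero(~first), np.flatnonzero(first)),
    ]


def _outer_cv_summary(
    X, y, support, folds, n_components, max_components, cv, rng
) -> StandardSummary:
    """Pooled held-out scores over the outer folds, summarized."""
    scores = np.empty(y.size)
    for tr, te in folds:
        m = fit_plsda(
            X[tr],
            y[tr],
            n_components=n_components,
            max_components=max_components,
            cv=cv,
            support=support,
            random_state=rng,
        )
        scores[te] = m.predict(X[te])
    return standard_summary(ScoredBatch(scores=scores, labels=y))


def _chain_supports(
    X, y, max_components, cv, max_candidate_supports, max_support_fraction, rng
):
    """Full-waveband PLS-DA -> SPRC -> adaptive LASSO path -> supports.

    Returns the selected latent-variable count and the distinct path
    supports, subsampled evenly across the size range.
    """
    a = select_n_components(
        X, y, max_components=max_components, cv=cv, random_state=rng, patience=2
    )
    full = fit_plsda(X, y, n_components=a)
    # truncated grid: the dense tail (supports beyond half the wavebands)
    # never yields a candidate, and dominates runtime on weak-signal data
    path = adaptive_lasso_path(X, y, full.sprc, n_alphas=60, eps=1e-2)
    p = X.shape[1]
    supports = [s for s in path.supports if s.size <= max_support_fraction * p]
    if len(supports) > max_candidate_supports:
        pick = np.round(np.linspace(0, len(supports) - 1, max_candidate_supports))
        supports = [supports[int(i)] for i in pick]
    return a, supports


def derive_candidates(
    dataset: LabeledDataset,
    variants: dict,
    max_components: int = 10,
    cv: int = 5,
    max_candidate_supports: int = 25,
    max_support_fraction: float = 0.5,
    random_state=None,
) -> CandidateSet:
    """Derive and evaluate sparse candidates from every variant matrix.

    For each variant the derivation chain (full-waveband PLS-DA -> SPRC
    -> adaptive LASSO path -> PLS-DA refit per distinct path support) is
    run *inside* each outer cross-validation fold: supports are selected
    and models refit on one duplicate capture and scored on the other,
    so held-out metrics carry no waveband-selection optimism.  Fold
    results are pooled per sparsity rank (position along the
    size-ordered path).  The deployable model of each candidate is the
    refit of the same-rank support derived from all rows; the
    full-support parent is kept as a non-sparse candidate.  Runtime is
    bounded by capping evaluated supports at ``max_candidate_supports``
    (spread over the size range) and ``max_support_fraction`` of the
    waveband count.
    """
    rng = np.random.default_rng(random_state)
    y = dataset.y.astype(float)
    folds = _capture_folds(dataset, rng)
    candidates: list[Candidate] = []
    for k in sorted(variants):
        mat: SpectraMatrix = variants[k]
        if mat.n_seeds != dataset.n:
            raise InputError(f"variant {k} rows do not match the dataset")
        X = mat.values
        p = X.shape[1]
        # per-fold nested derivation
        fold_a, fold_supports, parent_scores = [], [], np.empty(y.size)
        rank_scores: list[np.ndarray] = []
        for tr, te in folds:
            a_f, sups_f = _chain_supports(
                X[tr], y[tr], max_components, cv,
                max_candidate_supports, max_support_fraction, rng,
            )
            fold_a.append(a_f)
            fold_supports.append(sups_f)
            parent = fit_plsda(X[tr], y[tr], n_components=a_f)
            parent_scores[te] = parent.predict(X[te])
        n_ranks = min(len(s) for s in fold_supports)
        rank_scores = [np.empty(y.size) for _ in range(n_ranks)]
        for (tr, te), a_f, sups_f in zip(folds, fold_a, fold_supports):
            for r in range(n_ranks):
                sup = sups_f[r]
                m = fit_plsda(
                    X[tr], y[tr],
                    n_components=int(min(a_f, sup.size)),
                    support=sup,
                )
                rank_scores[r][te] = m.predict(X[te])

        # deployable models from the all-rows chain, aligned by rank
        a_all, sups_all = _chain_supports(
            X, y, max_components, cv,
            max_candidate_supports, max_support_fraction, rng,
        )
        parent_model = fit_plsda(
            X, y, n_components=a_all,
            wavelengths=mat.wavelengths, preprocess=mat.spec,
        )
        parent_model.meta = {"variant": k, "role": "non-sparse parent"}
        candidates.append(
            Candidate(
                model=parent_model,
                summary=standard_summary(
                    ScoredBatch(scores=parent_scores, labels=dataset.y)
                ),
                variant_index=k,
                support_size=p,
                is_sparse=False,
            )
        )
        for r in range(min(n_ranks, len(sups_all))):
            sup = sups_all[r]
            model = fit_plsda(
                X, y,
                n_components=int(min(a_all, sup.size)),
                support=sup,
                wavelengths=mat.wavelengths,
                preprocess=mat.spec,
            )
            model.meta = {"variant": k, "role": "sparse", "sparsity_rank": r}
            candidates.append(
                Candidate(
                    model=model,
                    summary=standard_summary(
                        ScoredBatch(scores=rank_scores[r], labels=dataset.y)
                    ),
                    variant_index=k,
                    support_size=int(sup.size),
                    is_sparse=True,
                )
            )
    ranking = _sort_ranking(candidates)
    return CandidateSet(
        candidates=candidates, ranking=ranking, dataset=dataset, variants=variants
    )


def _sort_ranking(candidates) -> np.ndarray:
    keys = [
        (-c.summary.sp, -c.summary.auc_rpr, c.support_size, i)
        for i, c in enumerate(candidates)
    ]
    return np.array([k[-1] for k in sorted(keys)], dtype=int)


def rank_candidates(
    candset: CandidateSet, iterations: int = 1, random_state=None
) -> CandidateSet:
    """Rank candidates; for ``iterations > 1``, aggregate median ranks
    over re-evaluations with resampled seed-level fold assignments.

    Deterministic given the seed.  Ties in median rank break by support
    size ascending, then stably by candidate order.
    """
    if iterations <= 1:
        candset.ranking = _sort_ranking(candset.candidates)
        return candset
    if candset.dataset is None or candset.variants is None:
        raise InputError("candidate set lacks data references for re-ranking")
    rng = np.random.default_rng(random_state)
    dataset, variants = candset.dataset, candset.variants
    y = dataset.y.astype(float)
    n_cand = len(candset.candidates)
    rank_hist = np.empty((iterations, n_cand))
    seeds = np.unique(dataset.seed_ids)
    for it in range(iterations):
        mask = np.zeros(seeds.size, dtype=bool)
        mask[rng.permutation(seeds.size)[: seeds.size // 2]] = True
        first = np.isin(dataset.seed_ids, seeds[mask])
        folds = [
            (np.flatnonzero(first), np.flatnonzero(~first)),
            (np.flatnonzero(~first), np.flatnonzero(first)),
        ]
        sums = []
        for c in candset.candidates:
            X = variants[c.variant_index].values
            sums.append(
                _outer_cv_summary(
                    X, y, c.model.support, folds, c.model.n_components, 8, 3, rng
                )
            )
        keys = [
            (-s.sp, -s.auc_rpr, candset.candidates[i].support_size, i)
            for i, s in enumerate(sums)
        ]
        order = [k[-1] for k in sorted(keys)]
        for pos, idx in enumerate(order):
            rank_hist[it, idx] = pos
    med = np.median(rank_hist, axis=0)
    keys = [
        (med[i], candset.candidates[i].support_size, i) for i in range(n_cand)
    ]
    candset.ranking = np.array([k[-1] for k in sorted(keys)], dtype=int)
    return candset


def score_seeds(model: PLSDAModel, spectra: SpectraMatrix) -> ScoredBatch:
    """Score a variant matrix with a fitted model.

    Refuses to score spectra whose preprocessing provenance differs
    from the model's -- spectra are never silently re-transformed.
    """
    if model.preprocess is not None and spectra.spec is not None:
        if model.preprocess != spectra.spec:
            raise PreprocessMismatchError(
                f"model expects {model.preprocess.label}, "
                f"spectra are {spectra.spec.label}"
            )
    if spectra.n_bands <= int(model.support.max()):
        raise InputError("spectra do not cover the model support")
    return ScoredBatch(
        scores=model.predict(spectra.values), seed_ids=spectra.seed_ids
    )


# ---------------------------------------------------------------------------
# Serialization


def model_to_json(model: PLSDAModel) -> str:
    payload = {
        "version": SERIALIZATION_VERSION,
        "n_components": model.n_components,
        "support": model.support.tolist(),
        "wavelengths_nm": model.wavelengths.tolist(),
        "coefficients": model.coefficients.tolist(),
        "intercept": model.intercept,
        "sprc": model.sprc.tolist(),
        "vip": model.vip.tolist(),
        "preprocess": (
            {
                "index": model.preprocess.index,
                "base": model.preprocess.base,
                "sg": model.preprocess.sg,
                "snv": model.preprocess.snv,
                "sg_first": model.preprocess.sg_first,
            }
            if model.preprocess is not None
            else None
        ),
        "meta": model.meta,
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def model_from_json(text: str) -> PLSDAModel:
    from .errors import FormatError

    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"model file is not valid JSON: {exc}") from exc
    if payload.get("version") != SERIALIZATION_VERSION:
        raise InputError(f"unsupported model version {payload.get('version')}")
    pp = payload.get("preprocess")
    preprocess = (
        PreprocessSpec(
            base=pp["base"], sg=pp["sg"], snv=pp["snv"], sg_first=pp["sg_first"]
        )
        if pp
        else None
    )
    return PLSDAModel(
        n_components=int(payload["n_components"]),
        support=np.array(payload["support"], dtype=int),
        wavelengths=np.array(payload["wavelengths_nm"], dtype=float),
        coefficients=np.array(payload["coefficients"], dtype=float),
        intercept=float(payload["intercept"]),
        sprc=np.array(payload["sprc"], dtype=float),
        vip=np.array(payload["vip"], dtype=float),
        preprocess=preprocess,
        meta=payload.get("meta", {}),
    )


def save_model(path, model: PLSDAModel) -> None:
    with open(path, "w") as fh:
        fh.write(model_to_json(model))


def load_model(path) -> PLSDAModel:
    with open(path) as fh:
        return model_from_json(fh.read())
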