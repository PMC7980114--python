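"""Environment-management decision support: counterfactual search for
minimal feature modifications that flip a predicted bad feeling of
health to good.

The pipeline has three stages:

1. a binary classifier (random forest by default) learns to predict the
   self-reported feeling of health (good/bad) from physiological and
   environmental features;
2. the features are partitioned into *modifiable* (patient- or
   device-controllable, from configuration), *correlated* (statistically
   tied to a modifiable feature, |Pearson r| >= threshold) — each with a
   linear model predicting it from the modifiable set — and
   *uncorrelated* (left untouched);
3. for a record predicted bad, NSGA-II searches over modification
   vectors, minimizing (total modification volume, number of modified
   features).  Correlated features are propagated through their linear
   models (residual-preservingly, so the zero modification is an exact
   identity), and a candidate is *admissible* only when the
   feeling-of-health model predicts good for the modified record.

Volume is the range-normalized absolute change summed over features
(sum |delta_i| / range_i, with range_i the training-data range), making
modifications of different units comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import train_test_split

from .errors import ContractError, InsufficientDataError, ParameterError

GOOD, BAD = "good", "bad"


# ---------------------------------------------------------------------------
# Feeling-of-health model
# ---------------------------------------------------------------------------

@dataclass
class HealthModel:
    classifier: RandomForestClassifier
    feature_columns: tuple[str, ...]
    holdout_accuracy: float
    seed: int

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        missing = set(self.feature_columns) - set(features.columns)
        if missing:
            raise ContractError(f"feature schema mismatch, missing {sorted(missing)}")
        return self.classifier.predict(features[list(self.feature_columns)])


def train_health_model(records: pd.DataFrame, seed: int = 0,
                       n_estimators: int = 100, test_frac: float = 0.2
                       ) -> HealthModel:
    """Fit the good/bad classifier and report stratified holdout accuracy."""
    labels = records["label"].astype(str)
    if set(labels.unique()) != {GOOD, BAD}:
        raise InsufficientDataError("training data must contain both labels")
    cols = tuple(c for c in records.columns if c != "label")
    X = records[list(cols)]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, labels, test_size=test_frac, stratify=labels, random_state=seed)
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                 n_jobs=1)
    clf.fit(X_tr, y_tr)
    acc = float(np.mean(clf.predict(X_te) == y_te) * 100.0)
    return HealthModel(clf, cols, acc, seed)


# ---------------------------------------------------------------------------
# Feature partition and propagation
# ---------------------------------------------------------------------------

@dataclass
class LinearPropagator:
    """OLS model predicting one correlated feature from the modifiable set."""

    feature: str
    coef: dict[str, float]
    intercept: float
    r_squared: float

    def shift(self, deltas: dict[str, float]) -> float:
        """Change in the predicted feature induced by modifiable deltas
        (the intercept and residual cancel, so zero deltas shift nothing)."""
        return sum(self.coef[m] * d for m, d in deltas.items() if m in self.coef)


@dataclass
class FeaturePartition:
    modifiable: tuple[str, ...]
    correlated: dict[str, LinearPropagator]
    uncorrelated: tuple[str, ...]
    threshold: float
    ranges: dict[str, float] = field(default_factory=dict)  # training-data ranges


def partition_features(records: pd.DataFrame, modifiable_names,
                       threshold: float = 0.3) -> FeaturePartition:
    """Split the schema into modifiable / correlated / uncorrelated.

    A non-modifiable feature is *correlated* when its largest absolute
    Pearson correlation with any modifiable feature reaches the
    threshold; constant features (undefined r) land in uncorrelated with
    a warning.  Linear models are filled in by
    :func:`fit_correlated_models`.
    """
    modifiable = tuple(modifiable_names)
    schema = [c for c in records.columns if c != "label"]
    unknown = set(modifiable) - set(schema)
    if unknown:
        raise ParameterError(f"modifiable names outside schema: {sorted(unknown)}")
    if not 0.0 < threshold < 1.0:
        raise ParameterError("correlation threshold must be in (0, 1)")

    correlated, uncorrelated = {}, []
    for f in schema:
        if f in modifiable:
            continue
        fv = records[f].to_numpy(dtype=float)
        if fv.std() < 1e-12:
            warnings.warn(f"feature {f!r} is constant; assigned uncorrelated")
            uncorrelated.append(f)
            continue
        best = max(abs(float(np.corrcoef(fv, records[m].to_numpy(dtype=float))[0, 1]))
                   if records[m].std() > 1e-12 else 0.0
                   for m in modifiable)
        if best >= threshold:
            correlated[f] = None  # model fitted later
        else:
            uncorrelated.append(f)
    ranges = {f: float(np.ptp(records[f].to_numpy(dtype=float))) for f in schema}
    part = FeaturePartition(modifiable, correlated, tuple(uncorrelated),
                            threshold, ranges)
    return fit_correlated_models(records, part)


def fit_correlated_models(records: pd.DataFrame,
                          partition: FeaturePartition) -> FeaturePartition:
    """OLS per correlated feature on all modifiable features (R^2 stored).

    A rank-deficient design is flagged with a warning; scikit-learn's
    least-squares solver already falls back to the pseudoinverse.
    """
    if len(records) < len(partition.modifiable) + 2:
        raise InsufficientDataError("too few records for the OLS fits")
    X = records[list(partition.modifiable)].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        warnings.warn("rank-deficient modifiable design; pseudoinverse fit")
    for f in list(partition.correlated):
        y = records[f].to_numpy(dtype=float)
        ols = LinearRegression().fit(X, y)
        partition.correlated[f] = LinearPropagator(
            f, dict(zip(partition.modifiable, map(float, ols.coef_))),
            float(ols.intercept_), float(ols.score(X, y)))
    return partition


def propagate(record: pd.Series, deltas: dict[str, float],
              partition: FeaturePartition) -> pd.Series:
    """Apply modifiable deltas and ripple them into correlated features.

    Correlated features are updated residual-preservingly:
    ``new_f = old_f + model(modified) - model(original)``, so zero deltas
    return the record unchanged, exactly.
    """
    bad = set(deltas) - set(partition.modifiable)
    if bad:
        raise ContractError(f"deltas on non-modifiable features: {sorted(bad)}")
    out = record.copy()
    for m, d in deltas.items():
        out[m] = record[m] + d
    for f, model in partition.correlated.items():
        out[f] = record[f] + model.shift(deltas)
    return out


def objectives(deltas: dict[str, float], ranges: dict[str, float]
               ) -> tuple[float, int]:
    """(volume, n_changed) of a modification vector."""
    volume = 0.0
    n_changed = 0
    for name, d in deltas.items():
        if d == 0.0:
            continue
        r = ranges.get(name, 0.0)
        if r <= 0:
            raise ParameterError(f"non-positive range for feature {name!r}")
        volume += abs(d) / r
        n_changed += 1
    return volume, n_changed


# ---------------------------------------------------------------------------
# Non-dominated sorting (NSGA-II machinery)
# ---------------------------------------------------------------------------

def _dominates(a, b) -> bool:
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def nondominated_sort(points) -> list[list[int]]:
    """Fast non-dominated sort (minimization); returns fronts of indices."""
    pts = [tuple(p) for p in points]
    n = len(pts)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(pts[i], pts[j]):
                dominated_by[i].append(j)
                n_dominating[j] += 1
            elif _dominates(pts[j], pts[i]):
                dominated_by[j].append(i)
                n_dominating[i] += 1
    fronts = [[i for i in range(n) if n_dominating[i] == 0]]
    while fronts[-1]:
        nxt = []
        for i in fronts[-1]:
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        fronts.append(nxt)
    return fronts[:-1]


def crowding_distance(points, front: list[int]) -> dict[int, float]:
    """Crowding distance of front members (boundary points get inf)."""
    if len(front) <= 2:
        return {i: np.inf for i in front}
    pts = np.asarray([points[i] for i in front], dtype=float)
    dist = np.zeros(len(front))
    for k in range(pts.shape[1]):
        order = np.argsort(pts[:, k], kind="stable")
        span = pts[order[-1], k] - pts[order[0], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            dist[order[1:-1]] += (pts[order[2:], k] - pts[order[:-2], k]) / span
    return dict(zip(front, dist))


# ---------------------------------------------------------------------------
# NSGA-II counterfactual search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NSGAConfig:
    population: int = 100
    generations: int = 100
    sbx_eta: float = 15.0
    sbx_prob: float = 0.9
    pm_eta: float = 20.0
    pm_prob: float | None = None   # default 1/n_vars
    mask_flip_prob: float | None = None  # default 1/n_vars


@dataclass(frozen=True)
class Modification:
    deltas: dict[str, float]
    volume: float
    n_changed: int
    admissible: bool


@dataclass
class ParetoFront:
    solutions: list[Modification]
    status: str   # 'ok' | 'already-good' | 'no-solution'

    def __iter__(self):
        return iter(self.solutions)

    def __len__(self):
        return len(self.solutions)


def _sbx(rng, a, b, lo, hi, eta, prob):
    """Simulated binary crossover, per-variable."""
    c1, c2 = a.copy(), b.copy()
    do = (rng.random(a.size) < 0.5) & (np.abs(a - b) > 1e-14)
    u = rng.random(a.size)
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    c1[do] = 0.5 * ((1 + beta[do]) * a[do] + (1 - beta[do]) * b[do])
    c2[do] = 0.5 * ((1 - beta[do]) * a[do] + (1 + beta[do]) * b[do])
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutate(rng, x, lo, hi, eta, prob):
    y = x.copy()
    do = rng.random(x.size) < prob
    for i in np.flatnonzero(do):
        if hi[i] <= lo[i]:
            continue
        u = rng.random()
        delta1 = (y[i] - lo[i]) / (hi[i] - lo[i])
        delta2 = (hi[i] - y[i]) / (hi[i] - lo[i])
        if u < 0.5:
            dq = (2 * u + (1 - 2 * u) * (1 - delta1) ** (eta + 1)) ** (1 / (eta + 1)) - 1
        else:
            dq = 1 - (2 * (1 - u) + 2 * (u - 0.5) * (1 - delta2) ** (eta + 1)) ** (1 / (eta + 1))
        y[i] = np.clip(y[i] + dq * (hi[i] - lo[i]), lo[i], hi[i])
    return y


def recommend(record: pd.Series, model: HealthModel, partition: FeaturePartition,
              bounds: dict[str, tuple[float, float]],
              config: NSGAConfig = NSGAConfig(), seed: int = 0) -> ParetoFront:
    """NSGA-II search for minimal admissible modifications of one record.

    The genome pairs a per-feature on/off mask with a real delta value
    (bounded per feature), so solutions touching few features are exactly
    representable.  Admissibility (model predicts good after propagation)
    is handled by constrained domination: admissible candidates dominate
    inadmissible ones outright.  Returns only admissible, mutually
    non-dominated, deduplicated modifications; an empty front carries a
    ``no-solution`` status, mirroring the minority of cases where no
    suitable modification exists within bounds.
    """
    if model.predict(record.to_frame().T)[0] == GOOD:
        return ParetoFront([], "already-good")
    names = [m for m in partition.modifiable if m in bounds]
    if not names:
        raise ParameterError("no bounded modifiable features to search over")
    lo = np.array([bounds[m][0] for m in names], dtype=float)
    hi = np.array([bounds[m][1] for m in names], dtype=float)
    n_vars = len(names)
    rng = np.random.default_rng(seed)
    pm_prob = config.pm_prob if config.pm_prob is not None else 1.0 / n_vars
    flip_prob = config.mask_flip_prob if config.mask_flip_prob is not None \
        else 1.0 / n_vars
    pop = config.population

    base_columns = {c: np.full(pop, float(record[c])) for c in model.feature_columns}

    def evaluate(masks: np.ndarray, values: np.ndarray):
        deltas = masks * values
        cand = pd.DataFrame({c: v.copy() for c, v in base_columns.items()})
        for k, m in enumerate(names):
            cand[m] = record[m] + deltas[:, k]
        for f, lin in partition.correlated.items():
            shift = sum(lin.coef[m] * deltas[:, k] for k, m in enumerate(names)
                        if m in lin.coef)
            cand[f] = record[f] + shift
        admissible = model.predict(cand) == GOOD
        objs = np.empty((len(deltas), 2))
        for i, dv in enumerate(deltas):
            v, nch = objectives(dict(zip(names, dv)), partition.ranges)
            objs[i] = (v, nch)
        return deltas, objs, admissible

    def rank_population(objs, admissible):
        """Constrained domination: feasible solutions are sorted among
        themselves and always precede infeasible ones."""
        ranks = np.full(len(objs), np.inf)
        crowd = np.zeros(len(objs))
        feas = np.flatnonzero(admissible)
        r = 0
        if feas.size:
            fo = objs[feas]
            # vectorized pairwise dominance (minimization, 2 objectives)
            dom = ((fo[:, None, :] <= fo[None, :, :]).all(-1)
                   & (fo[:, None, :] < fo[None, :, :]).any(-1))
            n_dominating = dom.sum(axis=0)
            remaining = np.ones(feas.size, dtype=bool)
            while remaining.any():
                front = np.flatnonzero(remaining & (n_dominating == 0))
                cd = crowding_distance([tuple(fo[i]) for i in range(feas.size)],
                                       list(front))
                for i in front:
                    ranks[feas[i]] = r
                    crowd[feas[i]] = cd[i]
                remaining[front] = False
                n_dominating = n_dominating - dom[front].sum(axis=0)
                r += 1
        ranks[np.flatnonzero(~admissible)] = r + 1
        return ranks, crowd

    # initial population: zero vector, single-feature candidates, random rest
    masks = np.zeros((pop, n_vars), dtype=float)
    values = rng.uniform(lo, hi, (pop, n_vars))
    for i in range(1, pop):
        if i <= n_vars:
            masks[i, (i - 1) % n_vars] = 1.0
        else:
            masks[i] = (rng.random(n_vars) < 2.0 / n_vars).astype(float)
    deltas, objs, adm = evaluate(masks, values)
    ranks, crowd = rank_population(objs, adm)

    # Pareto archive over (volume, n_changed): with an integer second
    # objective it reduces to the best volume seen per n_changed.
    archive: dict[int, tuple[np.ndarray, float]] = {}

    def archive_add(deltas, objs, adm):
        for dv, ob, ok in zip(deltas, objs, adm):
            if ok:
                nch = int(ob[1])
                if nch not in archive or ob[0] < archive[nch][1]:
                    archive[nch] = (dv.copy(), float(ob[0]))

    archive_add(deltas, objs, adm)

    def tournament():
        i, j = rng.integers(0, pop, 2)
        if ranks[i] < ranks[j] or (ranks[i] == ranks[j] and crowd[i] > crowd[j]):
            return i
        return j

    for _ in range(config.generations):
        child_masks = np.empty_like(masks)
        child_values = np.empty_like(values)
        for k in range(0, pop, 2):
            p1, p2 = tournament(), tournament()
            v1, v2 = values[p1], values[p2]
            if rng.random() < config.sbx_prob:
                v1, v2 = _sbx(rng, v1, v2, lo, hi, config.sbx_eta, config.sbx_prob)
            swap = rng.random(n_vars) < 0.5
            m1 = np.where(swap, masks[p2], masks[p1])
            m2 = np.where(swap, masks[p1], masks[p2])
            for child, (mv, vv) in zip((k, k + 1), ((m1, v1), (m2, v2))):
                if child >= pop:
                    break
                vv = _poly_mutate(rng, vv, lo, hi, config.pm_eta, pm_prob)
                flip = rng.random(n_vars) < flip_prob
                child_masks[child] = np.where(flip, 1.0 - mv, mv)
                child_values[child] = vv
        c_deltas, c_objs, c_adm = evaluate(child_masks, child_values)
        archive_add(c_deltas, c_objs, c_adm)

        all_masks = np.vstack([masks, child_masks])
        all_values = np.vstack([values, child_values])
        all_objs = np.vstack([objs, c_objs])
        all_adm = np.concatenate([adm, c_adm])
        all_ranks, all_crowd = rank_population(all_objs, all_adm)
        order = np.lexsort((-all_crowd, all_ranks))[:pop]
        masks, values = all_masks[order], all_values[order]
        objs, adm = all_objs[order], all_adm[order]
        ranks, crowd = all_ranks[order], all_crowd[order]

    if not archive:
        return ParetoFront([], "no-solution")
    items = [(nch, dv, vol) for nch, (dv, vol) in sorted(archive.items())]
    front_idx = nondominated_sort([(vol, nch) for nch, _, vol in items])[0]
    solutions = []
    for i in sorted(front_idx):
        nch, dv, vol = items[i]
        solutions.append(Modification(
            {m: float(d) for m, d in zip(names, dv) if d != 0.0},
            vol, nch, True))
    return ParetoFront(solutions, "ok")
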