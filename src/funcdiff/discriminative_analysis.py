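"""What separates the groups: SD pathway ranking and all-relevant selection.

Two complementary strategies extract discriminative features once units
are clustered or labeled:

* ranking pathways by the standard deviation of their coverage across a
  chosen set of units — a pathway completely present in some organisms
  and absent in others (an auxotrophy candidate) tops the list;
* Boruta-style all-relevant feature selection against a class response:
  every feature competes against "shadow" copies of itself (the same
  values, shuffled across samples) inside a random-forest importance
  ranking; features that repeatedly outrank the best shadow are
  confirmed, features that repeatedly fail are rejected, via two-sided
  binomial tests on the hit counts with Bonferroni correction.

The random forest itself comes from scikit-learn; only the shadow-feature
wrapper and its decision statistics live here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

from .feature_matrices import FeatureMatrix, split_row_label

__all__ = [
    "PathwayRanking",
    "SelectionResult",
    "SelectionError",
    "rank_pathways_by_sd",
    "compare_units_pathways",
    "top_units_for_pathway",
    "boruta_select",
    "build_response_vector",
    "VARIETY_COLOR",
]


class SelectionError(ValueError):
    pass


@dataclass
class PathwayRanking:
    """Pathways ordered by descending coverage SD across selected units."""

    table: pd.DataFrame  # index: pathway/feature id; columns: sd + one per unit

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.table.index)

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index_label="pathway")


def rank_pathways_by_sd(
    p: FeatureMatrix,
    units: Optional[Sequence[str]] = None,
    top_n: Optional[int] = None,
) -> PathwayRanking:
    """Rank rows of a coverage matrix by their SD across selected units.

    The SD uses the sample (n-1) denominator; ties break lexicographically
    by row id. At least two units must be selected.
    """
    cols = list(units) if units is not None else p.col_ids
    missing = [u for u in cols if u not in p.data.columns]
    if missing:
        raise SelectionError(f"unknown unit(s): {', '.join(missing)}")
    if len(cols) < 2:
        raise SelectionError("need at least 2 units to compute a coverage SD")
    sub = p.data[cols]
    sd = sub.std(axis=1, ddof=1)
    order = sorted(sub.index, key=lambda r: (-sd[r], r))
    if top_n is not None:
        order = order[:top_n]
    table = pd.concat([sd.rename("sd"), sub], axis=1).loc[order]
    return PathwayRanking(table=table)


def compare_units_pathways(
    p: FeatureMatrix,
    units: Sequence[str],
    top_n: int = 20,
    min_sd: float = 0.0,
) -> pd.DataFrame:
    """Heat-map-ready comparison of selected units on their top-SD pathways.

    Returns the ``top_n`` highest-SD pathways (strictly above ``min_sd``)
    with coverage expressed as a percentage in [0, 100] per unit.
    """
    ranking = rank_pathways_by_sd(p, units=units)
    tab = ranking.table[ranking.table["sd"] > min_sd].head(top_n)
    out = (tab[list(units)] * 100.0).round(6)
    out.insert(0, "sd", tab["sd"])
    return out


def top_units_for_pathway(
    pm: FeatureMatrix,
    pathway_id: str,
    top_n: int = 10,
    min_coverage: float = 0.05,
) -> pd.DataFrame:
    """Genera ranked by their coverage of one pathway (PM matrix rows).

    A genus qualifies when its coverage reaches ``min_coverage`` (default
    5%) in at least one sample; genera are ranked by their maximum
    coverage across samples and at most ``top_n`` are returned, with the
    per-sample coverages alongside.
    """
    rows = {}
    for rid in pm.row_ids:
        pid, genus = split_row_label(rid)
        if pid == pathway_id:
            rows[genus] = pm.data.loc[rid]
    if not rows:
        raise SelectionError(f"pathway {pathway_id!r} not present in matrix rows")
    tab = pd.DataFrame(rows).T
    tab.insert(0, "max_coverage", tab.max(axis=1))
    tab = tab[tab["max_coverage"] >= min_coverage]
    tab = tab.sort_values(
        by=["max_coverage"], ascending=False, kind="mergesort"
    ).iloc[: top_n]
    return tab


@dataclass
class SelectionResult:
    """Per-feature decisions from shadow-feature selection.

    ``decision`` maps each feature to confirmed/tentative/rejected;
    ``hit_count`` is the number of runs in which the feature outranked
    the best shadow while still undecided; ``importance_history`` holds
    one row per run (NaN once a feature is decided).
    """

    feature_ids: list[str]
    decision: dict[str, str]
    hit_count: dict[str, int]
    runs_used: int
    importance_history: np.ndarray
    confidence: float
    response_classes: list[str]

    def features(self, status: str) -> list[str]:
        return [f for f in self.feature_ids if self.decision[f] == status]

    @property
    def confirmed(self) -> list[str]:
        return self.features("confirmed")

    @property
    def rejected(self) -> list[str]:
        return self.features("rejected")

    @property
    def tentative(self) -> list[str]:
        return self.features("tentative")

    def to_tsv(self) -> str:
        lines = ["feature\tdecision\thit_count\tmedian_importance"]
        med = np.nanmedian(self.importance_history, axis=0)
        for i, f in enumerate(self.feature_ids):
            lines.append(
                f"{f}\t{self.decision[f]}\t{self.hit_count[f]}\t{med[i]:.6g}"
            )
        return "\n".join(lines) + "\n"

    def run_log(self, **params) -> str:
        return json.dumps(
            {
                "runs_used": self.runs_used,
                "confidence": self.confidence,
                "response_classes": self.response_classes,
                "n_confirmed": len(self.confirmed),
                "n_rejected": len(self.rejected),
                "n_tentative": len(self.tentative),
                "params": params,
            },
            indent=2,
            sort_keys=True,
        )


def _importances(
    model: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    if mode == "impurity":
        return model.feature_importances_
    if mode == "permutation":
        base = model.score(X, y)
        imp = np.empty(X.shape[1])
        Xp = X.copy()
        for j in range(X.shape[1]):
            saved = Xp[:, j].copy()
            Xp[:, j] = rng.permutation(saved)
            imp[j] = base - model.score(Xp, y)
            Xp[:, j] = saved
        return imp
    raise SelectionError(f"unknown importance mode {mode!r}")


def boruta_select(
    x: FeatureMatrix,
    y: Sequence[str],
    confidence: float = 0.99,
    max_runs: int = 2000,
    seed: int = 0,
    importance: str = "permutation",
    n_trees: int = 500,
) -> SelectionResult:
    """All-relevant feature selection by the shadow-feature scheme.

    Columns of ``x`` are samples, rows are features; ``y`` gives one class
    label per sample (at least two classes with two samples each). Each
    run appends a shuffled copy (shadow) of every feature, fits a
    random-forest classifier with class-balanced sampling, and scores a
    *hit* for each undecided feature whose importance exceeds the maximum
    shadow importance. After every run, two-sided binomial tests on the
    hit counts at significance ``1 - confidence``, Bonferroni-corrected
    across the undecided features, promote features to confirmed or
    demote them to rejected. The loop stops when nothing is undecided or
    after ``max_runs``; leftover features stay tentative, never silently
    promoted. Deterministic given ``seed``.

    The shadow pool always contains one shuffled copy of *every* original
    feature, decided or not, and rejected features leave the design
    matrix while confirmed ones remain. A full-size shadow pool keeps the
    hit null calibrated: even the most chance-correlated of m noise
    features beats the maximum of m fresh shadows only about half the
    time, so it cannot clear a binomial bar above one half — with a
    shrinking pool the max-shadow bar collapses late in the run and
    spurious confirmations accumulate.
    """
    y = np.asarray(list(y))
    if x.shape[1] != len(y):
        raise SelectionError(
            f"matrix has {x.shape[1]} samples but response has {len(y)}"
        )
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise SelectionError("response must have at least 2 classes")
    if counts.min() < 2:
        small = classes[counts < 2]
        raise SelectionError(
            f"class(es) with fewer than 2 samples: {', '.join(map(str, small))}"
        )
    if x.shape[0] < 2:
        raise SelectionError("need at least 2 features")
    if not 0.5 < confidence < 1.0:
        raise SelectionError("confidence must lie in (0.5, 1)")

    feature_ids = x.row_ids
    X_all = x.values.T  # samples x features
    n_feat = len(feature_ids)
    alpha = 1.0 - confidence
    rng = np.random.default_rng(seed)

    status = np.zeros(n_feat, dtype=int)  # 0 undecided, 1 confirmed, -1 rejected
    hits = np.zeros(n_feat, dtype=int)
    tested = np.zeros(n_feat, dtype=int)  # runs each feature was still undecided
    history: list[np.ndarray] = []
    runs = 0
    for runs in range(1, max_runs + 1):
        undecided = np.flatnonzero(status == 0)
        if len(undecided) == 0:
            runs -= 1
            break
        in_model = np.flatnonzero(status >= 0)  # undecided + confirmed
        X_real = X_all[:, in_model]
        shadows = np.column_stack(
            [rng.permutation(X_all[:, j]) for j in range(n_feat)]
        )
        X_run = np.hstack([X_real, shadows])
        model = RandomForestClassifier(
            n_estimators=n_trees,
            class_weight="balanced",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        model.fit(X_run, y)
        imp = _importances(model, X_run, y, importance, rng)
        real_imp = imp[: len(in_model)]
        shadow_max = imp[len(in_model):].max()
        row = np.full(n_feat, np.nan)
        row[in_model] = real_imp
        history.append(row)
        is_und = status[in_model] == 0
        hits[in_model[is_und]] += (real_imp[is_und] > shadow_max).astype(int)
        tested[undecided] += 1
        # binomial decision step, Bonferroni across currently undecided
        bonf = len(undecided)
        for j in undecided:
            p_two = binomtest(hits[j], tested[j], 0.5, alternative="two-sided").pvalue
            if p_two * bonf < alpha:
                status[j] = 1 if hits[j] * 2 > tested[j] else -1

    name = {1: "confirmed", -1: "rejected", 0: "tentative"}
    decision = {f: name[status[i]] for i, f in enumerate(feature_ids)}
    return SelectionResult(
        feature_ids=feature_ids,
        decision=decision,
        hit_count={f: int(hits[i]) for i, f in enumerate(feature_ids)},
        runs_used=runs,
        importance_history=(
            np.array(history) if history else np.empty((0, n_feat))
        ),
        confidence=confidence,
        response_classes=[str(c) for c in classes],
    )


#: Wine grape varieties of the study system and their color class.
VARIETY_COLOR = {"airen": "white", "bobal": "red", "tempranillo": "red"}


def build_response_vector(
    sample_metadata: pd.DataFrame, scheme: str = "red_white"
) -> list[str]:
    """Class labels per sample from a metadata table with a variety column.

    ``red_white`` maps each grape variety to its wine color (two classes:
    Airen is white; Bobal and Tempranillo are red); ``variety`` passes the
    varieties through (three classes). Unknown varieties are errors.
    """
    if "variety" not in sample_metadata.columns:
        raise SelectionError("metadata must have a 'variety' column")
    varieties = [str(v) for v in sample_metadata["variety"]]
    if scheme == "variety":
        return varieties
    if scheme != "red_white":
        raise SelectionError(f"unknown response scheme {scheme!r}")
    out = []
    for v in varieties:
        key = v.strip().lower()
        if key not in VARIETY_COLOR:
            raise SelectionError(f"unknown grape variety {v!r}")
        out.append(VARIETY_COLOR[key])
    return out
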