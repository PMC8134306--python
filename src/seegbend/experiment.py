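"""Evaluation protocol: stratified splits, cross-validation, hold-out rollout.

Cases (never individual electrodes) are split into a ~10% hold-out set
plus k near-equal folds; electrodes are stratified into six anatomical
groups by their entry/target metadata.  For each fold a model is trained
on the remaining folds and validated on the held fold; MSE_t (label
regression error) is reported on the hold-out point set per fold, and
every fold model then infers every hold-out electrode, giving
``n_electrodes x n_folds`` rollouts whose MSE_i distribution and
fraction below the 1 mm^2 threshold summarize trajectory accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import features as feat
from .geometry import compute_labels, trajectory_mse
from .inference import extract_window, infer_trajectory
from .models import (
    MCConfig, TrainConfig, TrainedModel,
    build_e2e_model, build_hcf_model, predict, train_model,
)
from .phantom import CaseSet, GROUPS, group_from_metadata

__all__ = [
    "SplitPlan", "make_splits", "stratify_groups", "build_point_dataset",
    "run_crossvalidation", "evaluate_holdout", "threshold_fraction",
    "render_report",
]


@dataclass
class SplitPlan:
    """Hold-out cases plus k disjoint folds over the remaining cases."""

    holdout_case_ids: list
    folds: list
    seed: int = 0

    def __post_init__(self):
        hold = set(self.holdout_case_ids)
        seen = set()
        for f in self.folds:
            fs = set(f)
            if fs & hold:
                raise ValueError("a fold overlaps the hold-out set")
            if fs & seen:
                raise ValueError("folds are not pairwise disjoint")
            seen |= fs

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def train_case_ids(self, fold: int) -> list:
        return [c for j, f in enumerate(self.folds) if j != fold for c in f]

    def val_case_ids(self, fold: int) -> list:
        return list(self.folds[fold])

    @property
    def all_case_ids(self) -> list:
        return list(self.holdout_case_ids) + [c for f in self.folds for c in f]


def make_splits(case_ids, seed: int = 0, n_folds: int = 10,
                holdout_frac: float = 0.10) -> SplitPlan:
    """Deterministic hold-out + k-fold split by case.

    The hold-out takes ``floor(holdout_frac * n)`` cases (86 cases ->
    8, as in the published protocol); the remainder is split into
    ``n_folds`` folds whose sizes differ by at most one.
    """
    case_ids = list(case_ids)
    n = len(case_ids)
    n_hold = int(np.floor(holdout_frac * n + 1e-9))
    if n - n_hold < n_folds:
        raise ValueError(
            f"{n} cases leave {n - n_hold} for {n_folds} folds; too few"
        )
    rng = np.random.default_rng(seed)
    order = [case_ids[i] for i in rng.permutation(n)]
    holdout = sorted(order[:n_hold])
    rest = order[n_hold:]
    folds = [sorted(f) for f in np.array_split(np.asarray(rest, dtype=object),
                                               n_folds)]
    return SplitPlan(holdout_case_ids=holdout,
                     folds=[list(f) for f in folds], seed=seed)


def stratify_groups(caseset: CaseSet) -> dict:
    """Map each electrode to exactly one of the six anatomical strata.

    Group membership is recomputed from the (entry lobe, target region)
    metadata; an electrode whose stored group disagrees with the rule is
    reported by id.
    """
    out = {g: [] for g in GROUPS}
    for case, e in caseset.iter_electrodes():
        try:
            g = group_from_metadata(e.entry_lobe, e.target_region)
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(
                f"unmappable region metadata for {case.case_id}/"
                f"{e.electrode_id}: {exc}"
            ) from exc
        if g != e.group:
            raise ValueError(
                f"electrode {case.case_id}/{e.electrode_id} carries group "
                f"{e.group!r} but its metadata maps to {g!r}"
            )
        out[g].append((case.case_id, e.electrode_id))
    return out


# ---------------------------------------------------------------------------
# point datasets


def build_point_dataset(caseset: CaseSet, case_ids, family: str,
                        source: str = "tissue", label_kind: str = "lu",
                        group: str | None = None) -> dict:
    """Per-interior-point training arrays for a set of cases.

    Returns ``{"inputs": {...}, "y": (N, 3), "case_ids": [...]}`` with
    inputs keyed ``features`` (HcF) or ``direction``/``window`` (E2E).
    """
    case_ids = set(case_ids)
    dirs, wins, feats, ys, provenance = [], [], [], [], []
    for case, e in caseset.iter_electrodes():
        if case.case_id not in case_ids:
            continue
        if group is not None and e.group != group:
            continue
        labels = compute_labels(e.implanted, e.rigid)
        y = labels.lu if label_kind == "lu" else labels.eb_hat
        ys.append(y)
        provenance.extend([case.case_id] * len(y))
        if family == "e2e":
            dirs.append(labels.v_hat)
            wins.extend(
                extract_window(case.volume, e.implanted.points[i],
                               source=source)
                for i in labels.indices
            )
        else:
            for i in labels.indices:
                feats.append(
                    feat.compute_point_features(e, int(i), case.volume).values
                )
    if not ys:
        return {"inputs": {}, "y": np.zeros((0, 3)), "case_ids": []}
    y = np.concatenate(ys)
    if family == "e2e":
        inputs = {"direction": np.concatenate(dirs),
                  "window": np.stack(wins)}
    else:
        inputs = {"features": np.asarray(feats)}
    return {"inputs": inputs, "y": y, "case_ids": provenance}


def _mse_on(model_net, dataset, mode="direct", mc_cfg=None,
            batch: int = 512) -> float:
    n = len(dataset["y"])
    total = 0.0
    for start in range(0, n, batch):
        sl = slice(start, min(start + batch, n))
        inputs = {k: v[sl] for k, v in dataset["inputs"].items()}
        pred = predict(model_net, inputs, mode=mode, mc_cfg=mc_cfg)
        mean = np.atleast_2d(pred.mean)
        diff = mean - dataset["y"][sl]
        total += float(np.sum(diff * diff))
    return total / (n * 3)


# ---------------------------------------------------------------------------
# cross-validation


def run_crossvalidation(
    caseset: CaseSet,
    split: SplitPlan,
    family: str = "e2e",
    source: str = "tissue",
    label_kind: str = "lu",
    group: str | None = None,
    cfg: TrainConfig | None = None,
    eval_mc: bool = False,
    mc_cfg: MCConfig | None = None,
    conv_channels: int = 8,
):
    """Train one model per fold; report MSE_t on the hold-out point set.

    ``group=None`` pools all strata (used for small cohorts where
    per-group folds would be too thin).  Folds with no matching training
    or validation electrodes are skipped with a warning row.  Returns
    ``(models_per_fold, metrics_rows)`` where metrics follow the
    mean-over-samples-and-components MSE convention.
    """
    cfg = cfg or TrainConfig(label_kind=label_kind)
    holdout_set = build_point_dataset(
        caseset, split.holdout_case_ids, family, source, label_kind, group
    )
    rows, models_per_fold = [], []
    for fold in range(split.n_folds):
        train_ids = split.train_case_ids(fold)
        train_set = build_point_dataset(caseset, train_ids, family, source,
                                        label_kind, group)
        val_set = build_point_dataset(caseset, split.val_case_ids(fold),
                                      family, source, label_kind, group)
        if len(train_set["y"]) == 0 or len(val_set["y"]) == 0:
            import warnings

            warnings.warn(
                f"fold {fold}: no electrodes of group {group!r}; skipping",
                stacklevel=2,
            )
            models_per_fold.append(None)
            continue
        assert not (set(train_set["case_ids"]) & set(split.holdout_case_ids))

        normalizer = None
        hold_eval = holdout_set
        if family == "hcf":
            normalizer = feat.fit_normalizer(train_set["inputs"]["features"])
            train_set = {
                **train_set,
                "inputs": {"features": normalizer.transform(
                    train_set["inputs"]["features"])},
            }
            val_set = {
                **val_set,
                "inputs": {"features": normalizer.transform(
                    val_set["inputs"]["features"])},
            }
            if len(holdout_set["y"]):
                hold_eval = {
                    **holdout_set,
                    "inputs": {"features": normalizer.transform(
                        holdout_set["inputs"]["features"])},
                }
            net = build_hcf_model(seed=cfg.seed + fold, dropout_p=cfg.dropout_p)
        else:
            net = build_e2e_model(conv_channels=conv_channels,
                                  seed=cfg.seed + fold,
                                  dropout_p=cfg.dropout_p)

        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 + fold})
        net, history = train_model(net, train_set, val_set, fold_cfg)
        trained = TrainedModel(
            net=net, label_kind=label_kind, family=family, source=source,
            normalizer=normalizer, train_config=fold_cfg, history=history,
        )
        models_per_fold.append(trained)

        row = {
            "group": group or "all", "model": family, "source": source,
            "label_kind": label_kind, "fold": fold,
            "mc": False,
            "mse_t": (_mse_on(net, hold_eval)
                      if len(hold_eval["y"]) else np.nan),
            "best_val_loss": history.attrs["best_val_loss"],
        }
        rows.append(row)
        if eval_mc and len(hold_eval["y"]):
            mcc = mc_cfg or MCConfig(seed=cfg.seed + 2000 + fold)
            rows.append({**row, "mc": True,
                         "mse_t": _mse_on(net, hold_eval, mode="mc",
                                          mc_cfg=mcc)})
    return models_per_fold, pd.DataFrame(rows)


def evaluate_holdout(
    models_per_fold: list,
    caseset: CaseSet,
    split: SplitPlan,
    mode: str = "direct",
    mc_cfg: MCConfig | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Infer every hold-out electrode with every fold model.

    Returns one row per (electrode, fold) with MSE_i, the rigid-baseline
    MSE for the same electrode, and metadata for per-group summaries.
    """
    if any(m is None for m in models_per_fold):
        raise ValueError("missing fold model(s); train all folds first")
    holdout = set(split.holdout_case_ids)
    rows = []
    for case, e in caseset.iter_electrodes():
        if case.case_id not in holdout:
            continue
        if group is not None and e.group != group:
            continue
        baseline = trajectory_mse(e.rigid, e.implanted)
        for fold, model in enumerate(models_per_fold):
            res = infer_trajectory(model, e, case.volume, mode=mode,
                                   mc_cfg=mc_cfg)
            rows.append({
                "case": case.case_id, "electrode": e.electrode_id,
                "group": e.group, "fold": fold, "mse_i": res.mse_i,
                "baseline_mse": baseline, "n_points": res.n_points,
                "out_of_volume": res.out_of_volume_events,
            })
    return pd.DataFrame(rows)


def threshold_fraction(mse_table: pd.DataFrame, threshold: float = 1.0,
                       column: str = "mse_i") -> float:
    """Fraction of rollouts at or below the reporting threshold (1 mm^2)."""
    if len(mse_table) == 0:
        raise ValueError("empty metrics table")
    return float((mse_table[column] <= threshold).mean())


def run_trajectory_validation_study(
    seed: int = 1,
    n_cases: int = 40,
    electrodes_per_case: int = 8,
    n_folds: int = 3,
    epochs: int = 50,
    label_kinds=("lu", "eb"),
    source: str = "tissue",
    family: str = "e2e",
):
    """Scaled-down trajectory-validation study on a phantom cohort.

    Generates a cohort, draws the hold-out + k-fold split, trains one
    pooled model per fold for each requested label kind, rolls out every
    hold-out electrode with every fold model, and returns
    ``{"dataset": CaseSet, "split": SplitPlan, label_kind: {"mse_t": df,
    "holdout": df}}``.  Every random stream derives from ``seed``.
    """
    from .phantom import generate_dataset

    dataset = generate_dataset(
        n_cases=n_cases, electrodes_per_case=electrodes_per_case, seed=seed
    )
    split = make_splits(dataset.case_ids, seed=seed, n_folds=n_folds)
    out = {"dataset": dataset, "split": split}
    for kind in label_kinds:
        cfg = TrainConfig(epochs=epochs, label_kind=kind, seed=seed)
        models, mse_t = run_crossvalidation(
            dataset, split, family=family, source=source, label_kind=kind,
            cfg=cfg,
        )
        holdout = evaluate_holdout(models, dataset, split)
        out[kind] = {"mse_t": mse_t, "holdout": holdout, "models": models}
    return out


def render_report(metrics: pd.DataFrame, scale: float = 1e3) -> str:
    """Cross-validation summary, groups x (model, source, label, MC).

    Cells show mean (SD) of MSE_t across folds, scaled x10^3 per the
    usual display convention for these small per-component errors.
    """
    df = metrics.copy()
    df["mse_scaled"] = df["mse_t"] * scale
    pivot = df.pivot_table(
        index="group",
        columns=["model", "source", "label_kind", "mc"],
        values="mse_scaled",
        aggfunc=["mean", "std"],
    )
    lines = ["# Cross-validation summary (MSE_t x 10^-3, mean (SD) across folds)",
             ""]
    means = pivot["mean"]
    stds = pivot["std"]
    header = ["group"] + [
        f"{m}/{s}/{l}/{'mc' if mc else 'direct'}" for (m, s, l, mc) in means.columns
    ]
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    for g in means.index:
        cells = [g]
        for col in means.columns:
            mu = means.loc[g, col]
            sd = stds.loc[g, col]
            cells.append(
                f"{mu:.2f} ({0.0 if np.isnan(sd) else sd:.2f})"
                if not np.isnan(mu) else "-"
            )
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
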