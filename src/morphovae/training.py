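"""Leakage-safe data partitioning, the training loop, alpha selection and a
budgeted random hyperparameter search."""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import TripletDataset
from .errors import DivergenceError
from .model import LossBreakdown, ModelConfig, MorphoVAE, one_hot
from .nn import make_optimizer

__all__ = [
    "SplitPlan",
    "TrainingHistory",
    "make_splits",
    "train_model",
    "select_alpha",
    "tune_hyperparameters",
    "default_search_space",
]

TEST_FRACTION = 1.0 / 3.0
VAL_FRACTION = 0.25  # of the non-test remainder


@dataclass
class SplitPlan:
    """Partition of parent specimen ids (both mirrored halves follow the id)."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int
    label_counts: pd.DataFrame | None = None

    def check(self) -> None:
        tr, va, te = set(self.train_ids), set(self.val_ids), set(self.test_ids)
        assert not (tr & va or tr & te or va & te), "partitions overlap"

    def to_dict(self) -> dict:
        return {
            "train_ids": list(self.train_ids),
            "val_ids": list(self.val_ids),
            "test_ids": list(self.test_ids),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitPlan":
        return cls(d["train_ids"], d["val_ids"], d["test_ids"], d.get("seed", 0))


@dataclass
class TrainingHistory:
    """Per-epoch losses on train and validation plus the best-epoch weights.

    ``best_epoch`` minimizes the validation value of the surrogate objective
    actually optimized (see ``MorphoVAE.objective``); ``val_objective`` keeps
    that trace alongside the as-reported loss breakdowns.
    """

    train: list[LossBreakdown] = field(default_factory=list)
    val: list[LossBreakdown] = field(default_factory=list)
    val_objective: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_weights: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for epoch, (tr, va) in enumerate(zip(self.train, self.val)):
            row = {"epoch": epoch}
            for tag, b in (("train", tr), ("val", va)):
                for k in ("e_rec", "e_reg", "e_c", "e_vae", "e_total"):
                    row[f"{tag}_{k}"] = getattr(b, k)
            rows.append(row)
        return pd.DataFrame(rows)


def _largest_remainder(counts: dict, fraction: float, total_target: int, rng) -> dict:
    """Per-label take sizes: floor of the quota, then largest remainders until
    the global target is met (seeded tie-break)."""
    labels = sorted(counts)
    quotas = {lab: counts[lab] * fraction for lab in labels}
    take = {lab: int(np.floor(quotas[lab])) for lab in labels}
    remainder = total_target - sum(take.values())
    if remainder > 0:
        frac = [(quotas[lab] - take[lab], rng.random(), lab) for lab in labels]
        frac.sort(key=lambda t: (-t[0], t[1]))
        for i in range(remainder):
            lab = frac[i % len(frac)][2]
            if take[lab] < counts[lab]:
                take[lab] += 1
    return take


def make_splits(manifest: pd.DataFrame, seed: int, val_seed: int | None = None) -> SplitPlan:
    """Stratified test / train / validation split over parent specimens.

    One-third of specimens go to test; of the remainder, 75% train and 25%
    validation, both by proportional extraction with largest-remainder
    rounding.  Both halves of a specimen always land in one partition because
    the plan operates on parent ids.  ``val_seed`` reshuffles only the
    train/validation stage (the test third stays tied to ``seed``).
    """
    if not {"specimen_id", "label"} <= set(manifest.columns):
        raise ValueError("manifest needs specimen_id and label columns")
    df = manifest.drop_duplicates("specimen_id")
    if df["label"].isna().any():
        raise ValueError("every specimen needs a label")

    by_label = {lab: sorted(g["specimen_id"]) for lab, g in df.groupby("label")}
    singletons = [lab for lab, ids in by_label.items() if len(ids) == 1]
    if singletons:
        warnings.warn(
            f"labels with a single specimen assigned to train: {singletons}", UserWarning
        )
    small = [lab for lab, ids in by_label.items() if 1 < len(ids) < 3]
    if small:
        warnings.warn(f"labels with fewer than 3 specimens: {small}", UserWarning)

    rng = np.random.default_rng(seed)
    forced_train = [by_label[lab][0] for lab in singletons]
    pool = {lab: ids for lab, ids in by_label.items() if lab not in singletons}
    counts = {lab: len(ids) for lab, ids in pool.items()}
    n = sum(counts.values())

    test_take = _largest_remainder(counts, TEST_FRACTION, int(round(n * TEST_FRACTION)), rng)
    test_ids, rest = [], {}
    for lab, ids in pool.items():
        ids = list(ids)
        rng.shuffle(ids)
        test_ids.extend(ids[: test_take[lab]])
        rest[lab] = ids[test_take[lab] :]

    rng2 = np.random.default_rng(seed if val_seed is None else val_seed)
    rest_counts = {lab: len(ids) for lab, ids in rest.items()}
    n_rest = sum(rest_counts.values())
    val_take = _largest_remainder(
        rest_counts, VAL_FRACTION, int(round(n_rest * VAL_FRACTION)), rng2
    )
    val_ids, train_ids = [], list(forced_train)
    for lab, ids in rest.items():
        ids = list(ids)
        rng2.shuffle(ids)
        val_ids.extend(ids[: val_take[lab]])
        train_ids.extend(ids[val_take[lab] :])

    stats = (
        df.assign(
            partition=lambda d: d["specimen_id"].map(
                {
                    **{i: "test" for i in test_ids},
                    **{i: "val" for i in val_ids},
                    **{i: "train" for i in train_ids},
                }
            )
        )
        .groupby(["label", "partition"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    plan = SplitPlan(sorted(train_ids), sorted(val_ids), sorted(test_ids), seed, stats)
    plan.check()
    return plan


def train_model(
    dataset: TripletDataset,
    config: ModelConfig,
    split: SplitPlan,
    alpha: float | None = None,
    verbose: bool = False,
) -> tuple[MorphoVAE, TrainingHistory]:
    """Minimize e_total for ``config.epochs`` epochs; keep best-validation weights.

    Returns the model with the best-validation-e_total weights loaded and the
    full per-epoch history.  Raises :class:`DivergenceError` on non-finite loss.
    """
    config = config.validate()
    alpha = config.alpha if alpha is None else float(alpha)
    model = MorphoVAE(config)
    optimizer = make_optimizer(config.optimizer, config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7EA1]))

    tr_idx = dataset.indices_for_parents(split.train_ids)
    va_idx = dataset.indices_for_parents(split.val_ids)
    if len(tr_idx) == 0 or len(va_idx) == 0:
        raise ValueError("empty train or validation partition for this dataset")
    Xtr, ytr = dataset.X[tr_idx], one_hot(dataset.y[tr_idx], config.n_classes)
    Xva, yva = dataset.X[va_idx], one_hot(dataset.y[va_idx], config.n_classes)

    history = TrainingHistory()
    best = np.inf
    for epoch in range(config.epochs):
        order = rng.permutation(len(Xtr))
        sums = np.zeros(3)
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            b = model.train_step(Xtr[sel], ytr[sel], optimizer, rng, alpha=alpha)
            if not np.isfinite(b.e_total):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}: {b}"
                )
            sums += len(sel) * np.array([b.e_rec, b.e_reg, b.e_c])
        e_rec, e_reg, e_c = sums / len(order)
        train_b = LossBreakdown.from_components(e_rec, e_reg, e_c, alpha)
        val_b = model.evaluate(Xva, yva, alpha=alpha)
        train_b.check(alpha)
        val_b.check(alpha)
        history.train.append(train_b)
        history.val.append(val_b)
        val_obj = model.objective(val_b, alpha)
        history.val_objective.append(val_obj)
        if val_obj < best:
            best = val_obj
            history.best_epoch = epoch
            history.best_weights = model.get_weights()
        if verbose:
            print(
                f"epoch {epoch:3d}  train e_total {train_b.e_total:.4f}  "
                f"val e_total {val_b.e_total:.4f}"
            )

    model.set_weights(history.best_weights)
    return model, history


def select_alpha(
    dataset: TripletDataset,
    alpha_grid,
    n_repeats: int,
    config: ModelConfig,
    seed: int = 0,
    e_c_tol: float = 0.10,
    e_vae_increase_tol: float = 0.05,
) -> pd.DataFrame:
    """Sweep alpha, training ``n_repeats`` models per value on resampled
    train/validation splits (the test third stays fixed).

    Returns a table with the best-model validation E_C and E_VAE per alpha,
    plus columns normalized so the grid maximum is 1.  The recommended alpha
    (``df.attrs['recommended_alpha']``) is the smallest value whose E_C is
    within ``e_c_tol`` (relative) of the grid minimum while the E_VAE increase
    over alpha=0 stays below ``e_vae_increase_tol``.
    """
    alpha_grid = sorted(float(a) for a in alpha_grid)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if 0.0 not in alpha_grid:
        warnings.warn("alpha grid lacks 0: E_VAE baseline for the increase rule is missing")

    manifest = dataset.parent_manifest()
    records = []
    for alpha in alpha_grid:
        for rep in range(n_repeats):
            split = make_splits(manifest, seed=seed, val_seed=seed + 1 + rep)
            cfg = replace(config, alpha=alpha, seed=config.seed + rep)
            model, history = train_model(dataset, cfg, split)
            best = history.val[history.best_epoch]
            records.append(
                {"alpha": alpha, "repeat": rep, "e_c": best.e_c, "e_vae": best.e_vae}
            )
    raw = pd.DataFrame(records)
    df = raw.groupby("alpha", as_index=False)[["e_c", "e_vae"]].mean()
    df["e_c_norm"] = df["e_c"] / df["e_c"].max()
    df["e_vae_norm"] = df["e_vae"] / df["e_vae"].max()

    recommended = None
    e_c_min = df["e_c"].min()
    baseline = df.loc[df["alpha"] == 0.0, "e_vae"]
    for row in df.itertuples(index=False):
        ok_c = row.e_c <= e_c_min * (1.0 + e_c_tol)
        ok_vae = (
            True
            if baseline.empty
            else row.e_vae <= float(baseline.iloc[0]) * (1.0 + e_vae_increase_tol)
        )
        if ok_c and ok_vae:
            recommended = row.alpha
            break
    df.attrs["recommended_alpha"] = recommended
    df.attrs["per_repeat"] = raw
    return df


def default_search_space() -> dict:
    """The structural ranges explored by the budgeted search."""
    return {
        "n_layers": [1, 2, 3, 4, 5],
        "filters": (16, 128),
        "activation": ["relu", "sigmoid", "tanh"],
        "optimizer": ["sgd", "adam", "rmsprop"],
    }


def _sample_config(space: dict, base: ModelConfig, rng: np.random.Generator) -> ModelConfig:
    n_layers = int(rng.choice(space.get("n_layers", [len(base.encoder_filters)])))
    lo, hi = space.get("filters", (16, 128))
    filters = [int(rng.integers(lo, hi + 1)) for _ in range(n_layers)]
    return replace(
        base,
        encoder_filters=filters,
        decoder_filters=filters[::-1],
        activation=str(rng.choice(space.get("activation", [base.activation]))),
        optimizer=str(rng.choice(space.get("optimizer", [base.optimizer]))),
    )


def tune_hyperparameters(
    dataset: TripletDataset,
    search_space: dict,
    budget_trials: int,
    config: ModelConfig,
    seed: int = 0,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Budgeted random search; returns (best config, full trial log).

    Each trial trains for ``config.epochs`` epochs on one fixed split and is
    scored by its best validation e_total.  Invalid candidates are rejected by
    config validation before any training happens.
    """
    if budget_trials < 1:
        warnings.warn("budget is 0: returning the base config untried")
        return config, pd.DataFrame()
    rng = np.random.default_rng(seed)
    split = make_splits(dataset.parent_manifest(), seed=seed)

    log = []
    best_cfg, best_val = None, np.inf
    for trial in range(budget_trials):
        try:
            cfg = _sample_config(search_space, config, rng).validate()
        except ValueError as exc:
            log.append({"trial": trial, "status": f"rejected: {exc}", "val_e_total": np.nan})
            continue
        _, history = train_model(dataset, cfg, split)
        score = history.val[history.best_epoch].e_total
        log.append(
            {
                "trial": trial,
                "status": "ok",
                "val_e_total": score,
                "encoder_filters": list(cfg.encoder_filters),
                "activation": cfg.activation,
                "optimizer": cfg.optimizer,
            }
        )
        if score < best_val:
            best_val, best_cfg = score, copy.deepcopy(cfg)
    return (best_cfg if best_cfg is not None else config), pd.DataFrame(log)
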