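"""End-to-end twin-database experiment: model object, results object, fixtures.

`TwinCultureExperiment` is the model-level entry point: it is built from an
`ExperimentConfig` (two synthetic "culture" database specs plus
preprocessing, augmentation, network and training settings) and its
``fit()`` executes the full pipeline — synthesize, standardize, augment,
extract frozen-backbone features, train one group of classifier heads per
database, evaluate matched and swapped confusion matrices, probe AU
tuning, and compute the cross-group statistics — returning an
`ExperimentReport` with every table and a ``summary()``.

Three named fixtures capture the study conditions: ``default-twin`` (two
cultures sharing happy/surprised/fearful/disgusted mappings but diverging
in angry and sad), ``identical-cultures`` (null control), and
``disjoint-cultures`` (maximal divergence control).

All randomness flows from one master seed through a SeedSequence
hierarchy: database A, database B, run group A, run group B; within each
run group, per-run split/init/batch/dropout streams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .au import EXPRESSIONS
from .augment import AugmentConfig, augment_labeled, desk_augment_config, resize_to_input
from .evaluate import (
    ConditionComparison,
    ConfusionMatrix,
    compare_correct_rates,
    confusion_matrix,
    swap_test_database,
)
from .faces import CultureMap, DatabaseSpec, generate_database, generate_probe_set
from .network import NetConfig, build_network
from .preprocess import PreprocessConfig, apply_oval_mask, histogram_adjust
from .probe import ProfileSet, group_profiles, normalize_profile, prepare_probe_features
from .profile_stats import (
    CorrelationMatrix,
    build_feature_matrix,
    correlate_with_confusion,
    cross_correlation_matrix,
    per_expression_correlations,
    reduce_profile,
    run_pca,
)
from .training import PreparedDatabase, RunRecord, TrainConfig, run_experiment

# ---------------------------------------------------------------------------
# culture fixtures

_SHARED = {
    "neutral": {},
    "happy": {12: 0.8},
    "surprised": {1: 0.6, 2: 0.6, 5: 0.6, 26: 0.7},
    "fearful": {1: 0.5, 2: 0.4, 4: 0.4, 5: 0.6, 20: 0.6, 25: 0.5},
    "disgusted": {9: 0.7, 10: 0.6, 17: 0.4},
}

#: Culture A: lip funneler (AU#22) marks anger; plain sadness.
CULTURE_A_MEANS = {**_SHARED, "angry": {4: 0.4, 22: 0.8}, "sad": {1: 0.5, 15: 0.7}}
#: Culture B: lip tightener (AU#23) marks anger; sadness includes AU#22.
CULTURE_B_MEANS = {**_SHARED, "angry": {4: 0.4, 23: 0.8}, "sad": {1: 0.5, 15: 0.7, 22: 0.6}}

#: Control culture sharing no active AU-expression association with A.
CULTURE_DISJOINT_MEANS = {
    "neutral": {},
    "happy": {6: 0.7, 24: 0.6},
    "surprised": {27: 0.8, 7: 0.5},
    "fearful": {9: 0.6, 11: 0.6},
    "sad": {23: 0.7, 2: 0.5},
    "angry": {16: 0.7, 10: 0.6},
    "disgusted": {26: 0.7, 15: 0.6},
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to run (or validate) one twin-database experiment."""

    database_a: DatabaseSpec
    database_b: DatabaseSpec
    preprocess: PreprocessConfig
    augment: AugmentConfig
    net: NetConfig
    train: TrainConfig
    master_seed: int = 0
    scale: str = "desk"

    def __post_init__(self):
        if self.database_a.image_size != self.database_b.image_size:
            raise ValueError("both databases must share the image size")
        if self.augment.input_size != self.net.input_size:
            raise ValueError("augment input size must match the network input size")

    def validate(self) -> dict:
        """Dry-run check: echo the settings without executing anything."""
        return {
            "databases": [self.database_a.name, self.database_b.name],
            "n_identities": [self.database_a.n_identities, self.database_b.n_identities],
            "image_size": self.database_a.image_size,
            "input_size": self.net.input_size,
            "fc_sizes": list(self.net.fc_sizes),
            "augment_variants": self.augment.n_variants,
            "batch_size": self.train.batch_size,
            "total_iterations": self.train.total_iterations,
            "lr_schedule": [list(x) for x in self.train.lr_schedule],
            "runs": self.train.runs,
            "split_proportions": list(self.train.split_proportions),
            "master_seed": self.master_seed,
            "scale": self.scale,
        }


def _config_for_scale(
    scale: str, culture_a: CultureMap, culture_b: CultureMap, master_seed: int,
    noise_sd: float = 0.1,
) -> ExperimentConfig:
    if scale == "full":
        # full protocol settings; validated with --dry-run, not executed here
        db = dict(n_identities=60, noise_sd=noise_sd, image_size=224)
        return ExperimentConfig(
            DatabaseSpec("A", culture_a, **db),
            DatabaseSpec("B", culture_b, **db, seed=1),
            PreprocessConfig(),
            AugmentConfig(input_size=224),
            NetConfig(fc_sizes=(4096, 4096, 7), input_size=224),
            TrainConfig(),
            master_seed=master_seed,
            scale=scale,
        )
    if scale == "desk":
        db = dict(n_identities=24, noise_sd=noise_sd, image_size=64)
        return ExperimentConfig(
            DatabaseSpec("A", culture_a, **db),
            DatabaseSpec("B", culture_b, **db, seed=1),
            PreprocessConfig(),
            desk_augment_config(input_size=64),
            NetConfig(fc_sizes=(128, 128, 7), input_size=64),
            TrainConfig(total_iterations=1500,
                        lr_schedule=((0, 1e-2), (500, 1e-3), (1000, 1e-4)),
                        runs=5, split_proportions=(16, 4, 4)),
            master_seed=master_seed,
            scale=scale,
        )
    if scale == "mini":
        db = dict(n_identities=18, noise_sd=noise_sd, image_size=64)
        return ExperimentConfig(
            DatabaseSpec("A", culture_a, **db),
            DatabaseSpec("B", culture_b, **db, seed=1),
            PreprocessConfig(),
            AugmentConfig(scales=(0.95, 1.0, 1.05),
                          offsets=((0.0, 0.0), (0.04, 0.0)),
                          reflections=(False, True), input_size=64),
            NetConfig(fc_sizes=(64, 64, 7), input_size=64),
            TrainConfig(total_iterations=1200,
                        lr_schedule=((0, 1e-2), (400, 1e-3), (800, 1e-4)),
                        runs=3, split_proportions=(12, 3, 3)),
            master_seed=master_seed,
            scale=scale,
        )
    raise ValueError(f"unknown scale {scale!r}; expected 'full', 'desk' or 'mini'")


FIXTURES = ("default-twin", "identical-cultures", "disjoint-cultures")


def fixture_suite(name: str, scale: str = "desk", master_seed: int = 0,
                  noise_sd: float = 0.1) -> ExperimentConfig:
    """Named experiment fixtures covering the default and control conditions."""
    ca = CultureMap.from_means(CULTURE_A_MEANS, sd=noise_sd)
    if name == "default-twin":
        cb = CultureMap.from_means(CULTURE_B_MEANS, sd=noise_sd)
    elif name == "identical-cultures":
        cb = ca
    elif name == "disjoint-cultures":
        cb = CultureMap.from_means(CULTURE_DISJOINT_MEANS, sd=noise_sd)
    else:
        raise KeyError(f"unknown fixture {name!r}; registry: {FIXTURES}")
    return _config_for_scale(scale, ca, cb, master_seed, noise_sd)


# ---------------------------------------------------------------------------
# pipeline stages

def prepare_database(spec: DatabaseSpec, preprocess: PreprocessConfig,
                     augment: AugmentConfig, net) -> PreparedDatabase:
    """Synthesize, standardize, augment and feature-extract one database."""
    images = generate_database(spec)
    label_idx = {label: i for i, label in enumerate(EXPRESSIONS)}
    aug_imgs, aug_labels, aug_ids = [], [], []
    eval_imgs, eval_labels, eval_ids = [], [], []
    for img in images:
        adj = np.clip(np.rint(histogram_adjust(img.pixels, preprocess)), 0, 255).astype(np.uint8)
        masked = apply_oval_mask(adj, preprocess)
        std_img = dataclasses.replace(img, pixels=masked)
        for v in augment_labeled(std_img, augment, preprocess.background):
            aug_imgs.append(v.pixels)
            aug_labels.append(label_idx[v.label])
            aug_ids.append(v.identity)
        eval_imgs.append(resize_to_input(masked, augment.input_size, preprocess.background))
        eval_labels.append(label_idx[img.label])
        eval_ids.append(img.identity)
    feats = _batched_features(net, np.stack(aug_imgs))
    eval_feats = _batched_features(net, np.stack(eval_imgs))
    return PreparedDatabase(
        name=spec.name,
        identities=tuple(dict.fromkeys(eval_ids)),
        feats=feats,
        labels=np.asarray(aug_labels),
        identity=np.asarray(aug_ids),
        eval_feats=eval_feats,
        eval_labels=np.asarray(eval_labels),
        eval_identity=np.asarray(eval_ids),
    )


def _batched_features(net, images: np.ndarray, batch: int = 256) -> np.ndarray:
    return np.concatenate([net.features(images[i:i + batch])
                           for i in range(0, len(images), batch)])


# ---------------------------------------------------------------------------
# results object

@dataclass
class ExperimentReport:
    """All tables produced by one fitted twin-database experiment."""

    config: ExperimentConfig
    records_a: list[RunRecord]
    records_b: list[RunRecord]
    matched_a: ConfusionMatrix
    matched_b: ConfusionMatrix
    swapped_a: ConfusionMatrix        # A-trained nets on database B test images
    swapped_b: ConfusionMatrix
    profiles_a: ProfileSet            # run-averaged, raw scale
    profiles_b: ProfileSet
    expression_correlations: pd.DataFrame
    corr_matrix_a_rows: CorrelationMatrix
    corr_vs_confusion_a_to_b: tuple[float, float]
    corr_vs_confusion_b_to_a: tuple[float, float]
    feature_matrix: pd.DataFrame
    pca: object
    matched_vs_swapped_a: ConditionComparison
    matched_vs_swapped_b: ConditionComparison
    anova_a: pd.DataFrame
    anova_b: pd.DataFrame

    @property
    def mean_correct(self) -> dict[str, float]:
        return {
            "matched_a": float(self.matched_a.correct_rates.mean()),
            "matched_b": float(self.matched_b.correct_rates.mean()),
            "swapped_a": float(self.swapped_a.correct_rates.mean()),
            "swapped_b": float(self.swapped_b.correct_rates.mean()),
        }

    def summary(self) -> str:
        mc = self.mean_correct
        lines = [
            "Twin-database facial-expression experiment",
            "=" * 58,
            f"databases: {self.config.database_a.name} / {self.config.database_b.name}"
            f"   scale: {self.config.scale}   master seed: {self.config.master_seed}",
            f"runs per group: {len(self.records_a)}   chance level: {1/7:.2f}",
            "",
            "mean correct rate (test):",
            f"  {self.config.database_a.name}-trained  matched {mc['matched_a']:.2f}"
            f"   swapped {mc['swapped_a']:.2f}"
            f"   (t = {self.matched_vs_swapped_a.t_statistic:.2f},"
            f" p = {self.matched_vs_swapped_a.t_p:.2g})",
            f"  {self.config.database_b.name}-trained  matched {mc['matched_b']:.2f}"
            f"   swapped {mc['swapped_b']:.2f}"
            f"   (t = {self.matched_vs_swapped_b.t_statistic:.2f},"
            f" p = {self.matched_vs_swapped_b.t_p:.2g})",
            "",
            "same-expression AU-profile correlations (Spearman rs):",
        ]
        for _, row in self.expression_correlations.iterrows():
            flag = "*" if row["significant"] else " "
            lines.append(f"  {row['expression']:>9}: rs = {row['rs']:+.2f}"
                         f"  (p = {row['p']:.2g}){flag}")
        ra, pa = self.corr_vs_confusion_a_to_b
        rb, pb = self.corr_vs_confusion_b_to_a
        lines += [
            "",
            "correlation-matrix vs swapped-confusion (49 pairs):",
            f"  {self.config.database_a.name}->"
            f"{self.config.database_b.name}: rs = {ra:+.2f} (p = {pa:.2g})",
            f"  {self.config.database_b.name}->"
            f"{self.config.database_a.name}: rs = {rb:+.2f} (p = {pb:.2g})",
            "",
            "PCA explained variance: "
            + ", ".join(f"PC{i+1} {v:.0%}" for i, v in
                        enumerate(self.pca.explained_variance_ratio[:3])),
        ]
        return "\n".join(lines)

    def to_dir(self, path: str | Path) -> None:
        """Write the report as labeled CSVs plus a JSON summary."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for tag, cm in [("matched_a", self.matched_a), ("matched_b", self.matched_b),
                        ("swapped_a", self.swapped_a), ("swapped_b", self.swapped_b)]:
            cm.to_dataframe().to_csv(path / f"confusion_{tag}.csv")
        self.expression_correlations.to_csv(path / "expression_correlations.csv", index=False)
        self.corr_matrix_a_rows.to_dataframe().to_csv(path / "correlation_matrix.csv")
        self.feature_matrix.to_csv(path / "feature_matrix.csv")
        self.profiles_a.to_dataframe().to_csv(path / "profiles_a.csv", index=False)
        self.profiles_b.to_dataframe().to_csv(path / "profiles_b.csv", index=False)
        self.anova_a.to_csv(path / "anova_a.csv")
        self.anova_b.to_csv(path / "anova_b.csv")
        curves = []
        for tag, records in (("a", self.records_a), ("b", self.records_b)):
            for rec in records:
                for epoch, (tr, va) in enumerate(zip(rec.epoch_train_acc,
                                                     rec.epoch_val_acc)):
                    curves.append({"group": tag, "run": rec.run_index,
                                   "epoch": epoch, "train_acc": tr, "val_acc": va})
        pd.DataFrame(curves).to_csv(path / "learning_curves.csv", index=False)
        pd.DataFrame(
            self.pca.scores,
            index=[f"{db}:{e}" for db, e in self.pca.columns],
            columns=[f"PC{i+1}" for i in range(self.pca.scores.shape[1])],
        ).to_csv(path / "pca_scores.csv")
        summary = {
            "config": self.config.validate(),
            "mean_correct": self.mean_correct,
            "corr_vs_confusion": {
                "a_to_b": list(self.corr_vs_confusion_a_to_b),
                "b_to_a": list(self.corr_vs_confusion_b_to_a),
            },
            "explained_variance_ratio": self.pca.explained_variance_ratio.tolist(),
        }
        (path / "summary.json").write_text(json.dumps(summary, indent=2))


# ---------------------------------------------------------------------------
# model object

class TwinCultureExperiment:
    """The full twin-database experiment as a fit-once model object."""

    def __init__(self, config: ExperimentConfig):
        self.config = config

    @classmethod
    def from_fixture(cls, name: str, scale: str = "desk",
                     master_seed: int = 0) -> "TwinCultureExperiment":
        return cls(fixture_suite(name, scale=scale, master_seed=master_seed))

    def validate(self) -> dict:
        return self.config.validate()

    def fit(self) -> ExperimentReport:
        cfg = self.config
        seeds = np.random.SeedSequence(cfg.master_seed).generate_state(4) % 2**31
        db_a = dataclasses.replace(cfg.database_a, seed=int(seeds[0]))
        db_b = dataclasses.replace(cfg.database_b, seed=int(seeds[1]))

        net = build_network(cfg.net)
        prep_a = prepare_database(db_a, cfg.preprocess, cfg.augment, net)
        prep_b = prepare_database(db_b, cfg.preprocess, cfg.augment, net)

        records_a = run_experiment(prep_a, cfg.net, cfg.train, int(seeds[2]))
        records_b = run_experiment(prep_b, cfg.net, cfg.train, int(seeds[3]))

        matched_a = confusion_matrix(records_a, prep_a, net)
        matched_b = confusion_matrix(records_b, prep_b, net)
        swapped_a = swap_test_database(
            records_a, prep_b, net,
            test_ids_per_run=[r.split.test_ids for r in records_b],
            train_database=prep_a.name)
        swapped_b = swap_test_database(
            records_b, prep_a, net,
            test_ids_per_run=[r.split.test_ids for r in records_a],
            train_database=prep_b.name)

        probe_set = generate_probe_set(size=db_a.image_size)
        probe_feats = prepare_probe_features(probe_set, net, cfg.preprocess)
        profiles_a = group_profiles(net, records_a, probe_feats)
        profiles_b = group_profiles(net, records_b, probe_feats)

        expr_corr = per_expression_correlations(profiles_a, profiles_b)
        corr_a_rows = cross_correlation_matrix(
            profiles_a, profiles_b, names=(prep_a.name, prep_b.name))
        # A-trained nets tested on B images: confusion rows are B's true
        # labels, so B profiles index the correlation rows.
        rs_ab = correlate_with_confusion(corr_a_rows.transpose(), swapped_a.matrix,
                                         confusion_true_group=prep_b.name)
        rs_ba = correlate_with_confusion(corr_a_rows, swapped_b.matrix,
                                         confusion_true_group=prep_a.name)

        norm_a = normalize_profile(profiles_a, scope="group")
        norm_b = normalize_profile(profiles_b, scope="group")
        reduced = [
            reduce_profile(ps.responses[e], unit=label, database=name)
            for ps, name in ((norm_a, prep_a.name), (norm_b, prep_b.name))
            for e, label in enumerate(EXPRESSIONS)
        ]
        fm = build_feature_matrix(reduced)
        pca = run_pca(fm, n_components=3)

        return ExperimentReport(
            config=cfg,
            records_a=records_a, records_b=records_b,
            matched_a=matched_a, matched_b=matched_b,
            swapped_a=swapped_a, swapped_b=swapped_b,
            profiles_a=profiles_a, profiles_b=profiles_b,
            expression_correlations=expr_corr,
            corr_matrix_a_rows=corr_a_rows,
            corr_vs_confusion_a_to_b=rs_ab,
            corr_vs_confusion_b_to_a=rs_ba,
            feature_matrix=fm,
            pca=pca,
            matched_vs_swapped_a=compare_correct_rates(matched_a, swapped_a),
            matched_vs_swapped_b=compare_correct_rates(matched_b, swapped_b),
            anova_a=compare_correct_rates(matched_a, swapped_a, test="anova").anova,
            anova_b=compare_correct_rates(matched_b, swapped_b, test="anova").anova,
        )
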