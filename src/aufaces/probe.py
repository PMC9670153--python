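"""AU tuning of the 7 output units: probe presentation and profile algebra.

Each trained network is shown the 20 x 11 probe battery (one AU swept at a
time on the average face, preprocessed exactly like the training images,
single centered presentation).  The raw pre-softmax scores of the seven
output units form a 7 x 20 x 11 response array; subtracting each unit's
response to the null image (all AUs off) zeroes the baseline, run
averages give the group's tuning profiles, and normalization rescales by
the maximum absolute response per unit or across the whole group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .au import AU_IDS, N_AUS, N_EXPRESSIONS
from .augment import resize_to_input
from .faces import ProbeStimulusSet
from .network import ExpressionNet
from .preprocess import PreprocessConfig, apply_oval_mask, histogram_adjust
from .training import RunRecord


@dataclass(frozen=True)
class ProfileSet:
    """Baseline-subtracted tuning profiles of the 7 output units.

    responses[u, a, k]: unit u's response to AU ``AU_IDS[a]`` at intensity
    index k (intensity 0 is the null image, response exactly 0).
    """

    responses: np.ndarray        # (7, 20, 11)
    n_runs: int = 1
    normalization: str = "raw"   # raw | unit | group

    def __post_init__(self):
        if self.responses.shape != (N_EXPRESSIONS, N_AUS, 11):
            raise ValueError(f"expected (7, 20, 11) responses, got {self.responses.shape}")

    def to_dataframe(self):
        """Long-format table: (unit, au, intensity, response) per row."""
        import pandas as pd

        from .au import EXPRESSIONS

        rows = [
            {"unit": EXPRESSIONS[u], "au": AU_IDS[a], "intensity": k / 10,
             "response": self.responses[u, a, k]}
            for u in range(N_EXPRESSIONS) for a in range(N_AUS) for k in range(11)
        ]
        return pd.DataFrame(rows)


def prepare_probe_features(
    probe_set: ProbeStimulusSet,
    net: ExpressionNet,
    config: PreprocessConfig | None = None,
) -> np.ndarray:
    """Backbone features of the probe battery: (20, 11, feature_dim).

    Probe images pass through the same standardization as training data
    (histogram adjustment + oval mask) and a single centered resize; no
    augmentation.
    """
    config = config or PreprocessConfig()
    imgs = []
    for au in AU_IDS:
        for img in probe_set.series[au]:
            adj = np.clip(np.rint(histogram_adjust(img, config)), 0, 255).astype(np.uint8)
            masked = apply_oval_mask(adj, config)
            imgs.append(resize_to_input(masked, net.config.input_size, config.background))
    feats = net.features(np.stack(imgs))
    return feats.reshape(N_AUS, 11, -1)


def probe_responses(net: ExpressionNet, record: RunRecord, probe_feats: np.ndarray) -> np.ndarray:
    """Raw pre-softmax responses of one trained run: (7, 20, 11)."""
    if probe_feats.shape[:2] != (N_AUS, 11):
        raise ValueError(f"expected (20, 11, D) probe features, got {probe_feats.shape}")
    net.set_fc_params(record.fc_params)
    feats = record.standardize(probe_feats.reshape(N_AUS * 11, -1))
    scores, _ = net.head_forward(feats)
    return scores.reshape(N_AUS, 11, N_EXPRESSIONS).transpose(2, 0, 1)


def subtract_baseline(raw: np.ndarray) -> np.ndarray:
    """Zero each unit's baseline by subtracting its null-image response.

    The intensity-0 response must be identical across the 20 series of a
    unit (they are the same image); a spread above 1e-6 signals a corrupt
    probe set and raises.
    """
    spread = raw[:, :, 0].max(axis=1) - raw[:, :, 0].min(axis=1)
    if np.any(spread > 1e-6):
        raise ValueError("null-image responses differ across AU series; probe set corrupt")
    return raw - raw[:, :1, :1]


def average_runs(arrays: list[np.ndarray]) -> ProfileSet:
    """Element-wise mean of per-run baseline-subtracted response arrays."""
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"mismatched response shapes: {shapes}")
    return ProfileSet(np.mean(arrays, axis=0), n_runs=len(arrays))


def normalize_profile(profiles: ProfileSet, scope: str = "unit") -> ProfileSet:
    """Rescale so the maximum absolute response is 1 per unit or per group."""
    r = profiles.responses
    if scope == "unit":
        m = np.abs(r).max(axis=(1, 2), keepdims=True)
        if np.any(m == 0):
            raise ValueError("all-zero profile cannot be normalized")
        return replace(profiles, responses=r / m, normalization="unit")
    if scope == "group":
        m = np.abs(r).max()
        if m == 0:
            raise ValueError("all-zero profile set cannot be normalized")
        return replace(profiles, responses=r / m, normalization="group")
    raise ValueError("scope must be 'unit' or 'group'")


def combine_profiles(a: ProfileSet, b: ProfileSet, op: str = "add") -> ProfileSet:
    """Element-wise sum or difference of two equally-normalized profile sets."""
    if a.normalization != b.normalization:
        raise ValueError(
            f"normalization tags differ: {a.normalization!r} vs {b.normalization!r}"
        )
    if op == "add":
        r = a.responses + b.responses
    elif op == "subtract":
        r = a.responses - b.responses
    else:
        raise ValueError("op must be 'add' or 'subtract'")
    return ProfileSet(r, n_runs=a.n_runs + b.n_runs, normalization=a.normalization)


def group_profiles(
    net: ExpressionNet, records: list[RunRecord], probe_feats: np.ndarray
) -> ProfileSet:
    """Probe every run, baseline-subtract, and average: one group's profiles."""
    arrays = [subtract_baseline(probe_responses(net, rec, probe_feats)) for rec in records]
    return average_runs(arrays)
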