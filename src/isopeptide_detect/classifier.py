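"""Logistic-regression site classifier over (rmsd, r_asa).

Training uses scikit-learn's LogisticRegression with default parameters
(L2 penalty, C = 1.0, no feature standardization); the fitted model is
persisted as a plain-text key=value file so prediction is a closed-form
sigmoid independent of any fitting-library version.  The classification
rule is strict: a site is called a bond only when its probability exceeds
the threshold (p equal to the threshold is negative).
"""
from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from .features import SiteFeatures

FEATURE_NAMES = ("rmsd", "r_asa")


class ClassifierError(Exception):
    pass


@dataclasses.dataclass
class LogisticModel:
    weights: np.ndarray            # one coefficient per feature
    intercept: float
    threshold: float = 0.5
    feature_names: tuple[str, ...] = FEATURE_NAMES
    training_meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.feature_names),):
            raise ClassifierError("one weight per feature required")
        if not 0.0 < self.threshold < 1.0:
            raise ClassifierError("threshold must lie in (0, 1)")

    def probability(self, features: SiteFeatures) -> float:
        x = features.as_array()
        if not np.all(np.isfinite(x)):
            raise ClassifierError(f"non-finite features: {x}")
        z = float(self.weights @ x + self.intercept)
        return float(1.0 / (1.0 + np.exp(-z)))

    def save(self, path: str | Path) -> None:
        lines = [
            f"feature_names={','.join(self.feature_names)}",
            "weights=" + ",".join(repr(float(w)) for w in self.weights),
            f"intercept={float(self.intercept)!r}",
            f"threshold={float(self.threshold)!r}",
        ]
        for key in sorted(self.training_meta):
            lines.append(f"meta.{key}={self.training_meta[key]}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "LogisticModel":
        fields: dict[str, str] = {}
        meta: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            if key.startswith("meta."):
                meta[key[5:]] = value
            else:
                fields[key] = value
        try:
            return cls(
                weights=np.array([float(w) for w in fields["weights"].split(",")]),
                intercept=float(fields["intercept"]),
                threshold=float(fields.get("threshold", "0.5")),
                feature_names=tuple(fields["feature_names"].split(",")),
                training_meta=meta,
            )
        except (KeyError, ValueError) as exc:
            raise ClassifierError(f"malformed model file {path}: {exc}") from exc


@dataclasses.dataclass
class Prediction:
    site: tuple
    template_id: str
    topology: str
    features: SiteFeatures
    probability: float
    is_bond: bool


def train(
    positives: list[SiteFeatures],
    negatives: list[SiteFeatures],
    seed: int = 0,
    threshold: float = 0.5,
) -> LogisticModel:
    """Maximum-likelihood logistic fit (L2, C = 1.0) on labeled features."""
    if not positives or not negatives:
        raise ClassifierError("both classes must be non-empty")
    x = np.array([f.as_array() for f in positives] + [f.as_array() for f in negatives])
    y = np.array([1] * len(positives) + [0] * len(negatives))
    clf = LogisticRegression(random_state=seed)
    clf.fit(x, y)
    return LogisticModel(
        weights=clf.coef_[0],
        intercept=float(clf.intercept_[0]),
        threshold=threshold,
        training_meta={
            "n_positives": str(len(positives)),
            "n_negatives": str(len(negatives)),
            "seed": str(seed),
            "standardized": "false",
        },
    )


def predict(model: LogisticModel, features: SiteFeatures, **site_info) -> Prediction:
    """Closed-form sigmoid probability; ``is_bond`` iff p strictly exceeds
    the model threshold."""
    p = model.probability(features)
    return Prediction(
        site=site_info.get("site", ()),
        template_id=site_info.get("template_id", ""),
        topology=site_info.get("topology", ""),
        features=features,
        probability=p,
        is_bond=p > model.threshold,
    )


def load_default_model() -> LogisticModel:
    """The bundled model, trained on the synthetic fixture corpus.

    It is a stand-in fitted on generated data (see the training metadata in
    the file); replace it via the --model option for any real-data use.
    """
    path = resources.files("isopeptide_detect.data").joinpath("default_model.txt")
    with resources.as_file(path) as p:
        return LogisticModel.load(p)
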