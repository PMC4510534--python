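"""End-to-end pipeline: images -> FPCA scores -> selection -> clustering.

The pipeline reads a cohort (image directory or feature CSV), extracts FPC
scores, optionally applies randomized leverage-score feature selection,
clusters with k-means or spectral clustering, evaluates against optional
ground-truth labels, and writes all artifacts (scores, plan, assignments,
report, log) with full seed/config provenance. Identical config and seed
produce identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import build_fourier_basis
from .cluster import evaluate, run_kmeans, run_spectral
from .errors import CohortInconsistencyError, InvalidArgumentError
from .feature_select import FeatureMatrix, select_features
from .fpca import center_coefficients, compute_scores, eigen_decompose, fit_coefficients
from .signals import ImageSignal

__all__ = ["RunConfig", "read_images", "run_pipeline"]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
_LUMA = np.array([0.2126, 0.7152, 0.0722])  # Rec. 709 luminance weights


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one input source."""

    image_dir: str | None = None
    feature_csv: str | None = None
    basis_K: int = 15
    n_components: int | None = None  # None: smallest J with >= var_threshold
    var_threshold: float = 0.95
    method: str = "kmeans"  # kmeans | spectral
    feature_selection: str = "randomized"  # none | randomized
    k: int = 2
    epsilon: float = 1 / 3
    r_override: int | None = None
    restarts: int = 25
    seed: int = 0
    output_dir: str = "imgfpc_out"
    truth_csv: str | None = None

    def validate(self) -> None:
        if (self.image_dir is None) == (self.feature_csv is None):
            raise InvalidArgumentError(
                "exactly one of image_dir / feature_csv must be given"
            )
        if self.method not in ("kmeans", "spectral"):
            raise InvalidArgumentError(f"unknown method {self.method!r}")
        if self.feature_selection not in ("none", "randomized"):
            raise InvalidArgumentError(
                f"unknown feature_selection {self.feature_selection!r}"
            )
        if self.k < 1:
            raise InvalidArgumentError("k must be >= 1")
        if not 0 < self.epsilon <= 1:
            raise InvalidArgumentError("epsilon must be in (0, 1]")
        if not 0 < self.var_threshold <= 1:
            raise InvalidArgumentError("var_threshold must be in (0, 1]")


def _to_gray_unit(arr: np.ndarray) -> np.ndarray:
    """RGB(A) -> luminance grayscale; integer intensities -> [0, 1]."""
    a = np.asarray(arr)
    if a.ndim == 3:
        a = a[..., :3] @ _LUMA if a.shape[2] >= 3 else a[..., 0]
    if np.issubdtype(np.asarray(arr).dtype, np.integer):
        a = a.astype(float) / np.iinfo(np.asarray(arr).dtype).max
    else:
        a = a.astype(float)
    return a


def read_images(directory: str | Path) -> list[ImageSignal]:
    """Read all images in a directory in sorted-filename order.

    RGB images are converted to grayscale by luminance weighting; 8/16-bit
    integer intensities are rescaled to [0, 1]. All images must share one
    pixel grid.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if len(paths) < 2:
        raise CohortInconsistencyError(
            f"need at least 2 images in {directory}, found {len(paths)}"
        )
    images = [
        ImageSignal(values=_to_gray_unit(iio.imread(p)), name=p.stem) for p in paths
    ]
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        offenders = ", ".join(f"{im.name}: {im.shape}" for im in images)
        raise CohortInconsistencyError(
            f"mixed image dimensions {sorted(shapes)} ({offenders})"
        )
    return images


def _load_features(config: RunConfig) -> tuple[np.ndarray, list[str], list[str], dict]:
    """Return (A, sample_ids, feature_names, fpca_sidecar)."""
    if config.feature_csv is not None:
        df = pd.read_csv(config.feature_csv, index_col=0)
        return (
            df.to_numpy(dtype=float),
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            {},
        )
    images = read_images(config.image_dir)
    basis = build_fourier_basis(config.basis_K)
    coef = center_coefficients(fit_coefficients(images, basis))
    K2 = config.basis_K**2
    J_max = min(coef.n_images - 1, K2)
    es = eigen_decompose(coef, J=J_max)
    sm = compute_scores(coef, es)
    if config.n_components is not None:
        J = min(int(config.n_components), J_max)
    else:
        cum = np.cumsum(sm.variance_explained)
        J = int(np.searchsorted(cum, config.var_threshold) + 1)
        J = min(J, J_max)
    sidecar = {
        "eigenvalues": es.eigenvalues.tolist(),
        "variance_explained": sm.variance_explained.tolist(),
        "n_components_used": J,
        "basis_K": config.basis_K,
    }
    return (
        sm.xi[:, :J],
        [im.name for im in images],
        [f"FPC{j + 1}" for j in range(J)],
        sidecar,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline and write artifacts to output_dir.

    Artifacts: ``scores.csv`` (features used for clustering),
    ``fpca.json`` (eigenvalues / variance explained, image runs only),
    ``selection_plan.json``, ``assignments.csv``, ``report.json`` and
    ``run_log.json``. Returns the report as a dict.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    A, sample_ids, feature_names, sidecar = _load_features(config)
    pd.DataFrame(A, index=sample_ids, columns=feature_names).to_csv(
        out / "scores.csv", index_label="sample_id"
    )
    if sidecar:
        (out / "fpca.json").write_text(json.dumps(sidecar, indent=2))

    plan_record: dict = {"feature_selection": config.feature_selection}
    if config.feature_selection == "randomized":
        fm = FeatureMatrix(A, feature_names=feature_names)
        C, plan, _ = select_features(
            fm, k=config.k, epsilon=config.epsilon,
            seed=config.seed, r=config.r_override,
        )
        cluster_input = C
        plan_record.update(plan.to_dict())
        plan_record["k"] = config.k
        plan_record["selected_features"] = [
            feature_names[i] for i in plan.indices
        ]
    else:
        cluster_input = A
    (out / "selection_plan.json").write_text(json.dumps(plan_record, indent=2))

    if config.method == "kmeans":
        model = run_kmeans(
            cluster_input, k=config.k, restarts=config.restarts, seed=config.seed
        )
    else:
        model = run_spectral(
            cluster_input, k=config.k, seed=config.seed, restarts=config.restarts
        )
    pd.DataFrame(
        {"sample_id": sample_ids, "cluster": model.assignment}
    ).to_csv(out / "assignments.csv", index=False)

    report: dict = {
        "objective": model.objective,
        "k": config.k,
        "method": config.method,
        "feature_selection": config.feature_selection,
        "n_samples": len(sample_ids),
        "n_features_clustered": int(np.atleast_2d(cluster_input).shape[1]),
        "seed": config.seed,
    }
    if config.truth_csv is not None:
        tdf = pd.read_csv(config.truth_csv)
        truth = (
            tdf.set_index(tdf.columns[0])
            .loc[sample_ids, tdf.columns[1]]
            .to_numpy()
        )
        classes = {c: j for j, c in enumerate(pd.unique(truth))}
        rep = evaluate(model, np.array([classes[c] for c in truth]))
        report.update(
            accuracy=rep.accuracy,
            sensitivity=rep.sensitivity,
            specificity=rep.specificity,
            confusion=rep.confusion.tolist(),
            per_class_recall=rep.per_class_recall,
        )
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "run_log.json").write_text(
        json.dumps({"config": asdict(config)}, indent=2)
    )
    return report
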