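"""Batch orchestration: simulate/load -> project -> segment -> score -> report.

Runs the whole quantification over a list of image stacks (from disk or
from the synthetic generator), producing one tidy report row per nucleus
(fluctuation index, per-direction fractions, QC flags), optional contour
overlay PNGs, and per-group summaries with a Mann-Whitney U comparison.
Per-image failures are logged and skipped so one bad field never aborts a
batch; everything is deterministic given the seed in the config.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ContractError
from .metric import fluctuation_index, sample_contour_intensity
from .segmentation import SegmentationConfig, SnakeParams, segment_nuclei
from .stacks import ImageStack, max_intensity_projection, read_stack, ROLE_REFERENCE, ROLE_TEST

logger = logging.getLogger("laminafluct")

REPORT_COLUMNS = [
    "image_id", "nucleus_id", "group", "n_points",
    "fraction_12", "fraction_21", "index", "threshold", "qc",
]


@dataclass
class RunConfig:
    """Everything a batch run needs; round-trips through a single YAML file."""

    role_map: dict[str, int] = field(default_factory=lambda: {"counterstain": 0, "reference": 1, "test": 2})
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    threshold: float = 0.15
    seed: int = 0
    output_dir: str | None = None
    write_overlays: bool = False
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        seg = raw.pop("segmentation", {})
        snake = seg.pop("snake", {}) if isinstance(seg, dict) else {}
        config = cls(**raw)
        config.segmentation = SegmentationConfig(**seg, snake=SnakeParams(**snake))
        return config


def analyze_stack(
    stack: ImageStack,
    config: RunConfig,
    image_id: str = "image",
    group: str | None = None,
) -> pd.DataFrame:
    """Segment one stack and score every nucleus; returns report rows."""
    contours = segment_nuclei(stack, config.segmentation)
    ref_img = max_intensity_projection(stack, ROLE_REFERENCE)
    test_img = max_intensity_projection(stack, ROLE_TEST)
    rows = []
    for i, contour in enumerate(contours):
        ref_profile = sample_contour_intensity(ref_img, contour)
        test_profile = sample_contour_intensity(test_img, contour)
        result = fluctuation_index(ref_profile, test_profile, config.threshold)
        rows.append({
            "image_id": image_id,
            "nucleus_id": i,
            "group": group,
            "n_points": contour.n_points,
            "fraction_12": result.fraction_12,
            "fraction_21": result.fraction_21,
            "index": result.index,
            "threshold": result.threshold,
            "qc": "ok",
        })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def run_analysis(config: RunConfig, inputs) -> pd.DataFrame:
    """Run the full quantification over a batch.

    ``inputs`` is an iterable of either TIFF paths or
    ``(ImageStack, image_id, group)`` triples (group may be None).  Writes
    ``report.csv``, the resolved config, and optional overlay PNGs to
    ``config.output_dir`` when set.  Raises only if every image fails.
    """
    logger.setLevel(config.log_level)
    frames, items, failures = [], [], 0
    for k, item in enumerate(inputs):
        if isinstance(item, (str, Path)):
            image_id, group = Path(item).stem, None
            loader = lambda item=item: read_stack(item, config.role_map)
        else:
            stack, image_id, group = item
            loader = lambda stack=stack: stack
        try:
            stack = loader()
            frame = analyze_stack(stack, config, image_id=image_id, group=group)
            if frame.empty:
                logger.warning("no nuclei detected in %s", image_id)
            frames.append(frame)
            items.append((stack, image_id, frame))
            logger.info("%s: %d nuclei", image_id, len(frame))
        except Exception:
            failures += 1
            logger.exception("image %s failed; skipping", image_id)
    if not frames:
        raise ContractError("every input image failed to analyze")
    report = pd.concat(frames, ignore_index=True)
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "report.csv", index=False)
        config.to_yaml(outdir / "config.yaml")
        if config.write_overlays:
            for stack, image_id, frame in items:
                _write_overlay(stack, config, outdir / f"{image_id}_overlay.png")
    return report


def _write_overlay(stack: ImageStack, config: RunConfig, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = max_intensity_projection(stack, ROLE_REFERENCE)
    contours = segment_nuclei(stack, config.segmentation)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(ref.data, cmap="gray")
    for c in contours:
        closed = np.vstack([c.points, c.points[:1]])
        ax.plot(closed[:, 1], closed[:, 0], lw=1.0)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def summarize_groups(
    report: pd.DataFrame,
    alternative: str = "two-sided",
    min_group_size: int = 3,
) -> tuple[pd.DataFrame, float | None]:
    """Per-group index summaries plus a Mann-Whitney U comparison.

    Returns (summary table, p-value).  With fewer than two groups of at
    least ``min_group_size`` nuclei the p-value is None and a warning is
    issued.  With ``alternative="greater"`` the test asks whether the
    first-appearing group's indices tend to exceed the second's.
    """
    if "group" not in report.columns or report["group"].isna().all():
        warnings.warn("no group labels; returning overall summary only", stacklevel=2)
        groups = {"all": report["index"].to_numpy()}
    else:
        ordered = report["group"].dropna().unique().tolist()
        groups = {g: report.loc[report.group == g, "index"].to_numpy() for g in ordered}
    rows = []
    for name, vals in groups.items():
        q1, q3 = (np.percentile(vals, [25, 75]) if len(vals) else (np.nan, np.nan))
        rows.append({
            "group": name, "n": len(vals),
            "mean": float(np.mean(vals)) if len(vals) else np.nan,
            "median": float(np.median(vals)) if len(vals) else np.nan,
            "iqr_low": float(q1), "iqr_high": float(q3),
        })
    summary = pd.DataFrame(rows)
    eligible = [name for name, vals in groups.items() if len(vals) >= min_group_size]
    if len(eligible) != 2:
        warnings.warn(
            f"need exactly 2 groups with >= {min_group_size} nuclei for a comparison; "
            f"got {len(eligible)} — summary only", stacklevel=2,
        )
        return summary, None
    a, b = (groups[name] for name in eligible)
    _, p = stats.mannwhitneyu(a, b, alternative=alternative)
    return summary, float(p)
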