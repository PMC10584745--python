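"""End-to-end synthetic study orchestration.

``run_study`` drives the whole pipeline from a single config: synthesize
phantom references, window them to display images, build the distortion
grid, score every pair with the nine metrics, simulate the observer panel,
collapse marks to subjective scores, and run the evaluation harness.  All
randomness fans out from one base seed through fixed per-stage offsets, so
any stage can be reproduced in isolation and a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ct_prep import WindowSetting, crop_background, save_display_png, window_to_display
from .distortions import BLUR_GRID, NOISE_GRID, generate_grid
from .dscqs import icc_2_1, ratings_matrix, subjective_table
from .iqa_eval import evaluate
from .metrics import METRIC_NAMES, compute_all
from .observer_sim import (
    ObserverModelParams,
    PhantomSpec,
    default_reference_specs,
    make_phantom,
    simulate_marks,
)

# per-stage seed offsets (base_seed + offset), keeping derived seeds < 2^31
_STAGE_OFFSETS = {"phantom": 0, "distort": 10_000, "marks": 20_000}


@dataclass
class StudyConfig:
    """Everything needed to reproduce a study run."""

    base_seed: int = 0
    phantom_size: int = 512
    n_references: int = 6
    noise_levels: tuple[float, ...] = NOISE_GRID
    blur_levels: tuple[float, ...] = BLUR_GRID
    distortion_order: str = "blur_first"
    crop_threshold: int | None = None  # None: derived from each window (air + 10)
    crop_margin: int = 2
    observer: ObserverModelParams = field(default_factory=ObserverModelParams)
    groups: tuple[str, ...] = ("all", "noise", "blur", "head", "chest", "abdomen")
    alpha: float = 0.05
    save_images: bool = False
    out_dir: str = "study_out"

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["observer"] = dataclasses.asdict(self.observer)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        d = yaml.safe_load(text)
        obs = ObserverModelParams(**d.pop("observer", {}))
        for key in ("noise_levels", "blur_levels", "groups"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(observer=obs, **d)


def stage_seed(config: StudyConfig, stage: str) -> int:
    return (config.base_seed + _STAGE_OFFSETS[stage]) % (2**31 - 1)


def build_references(config: StudyConfig):
    specs = default_reference_specs(
        size=config.phantom_size, base_seed=stage_seed(config, "phantom")
    )[: config.n_references]
    displays = []
    for spec in specs:
        raw = make_phantom(spec)
        disp = window_to_display(raw, WindowSetting.for_site(spec.site))
        displays.append(disp)
    return specs, displays


def score_pairs(pairs) -> pd.DataFrame:
    rows = []
    for pair in pairs:
        vec = compute_all(pair)
        row = {
            "pair_id": pair.pair_id,
            "site": pair.site,
            "source_id": pair.reference.source_id,
            "sigma_noise": pair.spec.sigma_noise,
            "sigma_blur": pair.spec.sigma_blur,
            "seed": pair.spec.seed,
        }
        row.update(vec.as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> Path:
    """Run the full pipeline and write all artifacts under ``config.out_dir``.

    Outputs: ``config.yaml``, ``manifest.csv``, ``scores.csv``,
    ``subjective.csv``, ``records.csv`` (join of both), ``summary.csv``,
    ``significance_*.csv``, ``icc.json``, ``run_log.json`` and a ``STATUS``
    sentinel that reads ``ok`` only when every stage completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status = out / "STATUS"
    status.write_text("running\n")
    try:
        (out / "config.yaml").write_text(config.to_yaml())

        _specs, refs = build_references(config)
        pairs = generate_grid(
            refs,
            noise_levels=tuple(config.noise_levels),
            blur_levels=tuple(config.blur_levels),
            base_seed=stage_seed(config, "distort"),
            order=config.distortion_order,
            crop=True,
            crop_threshold=config.crop_threshold,
            crop_margin=config.crop_margin,
        )

        manifest = pd.DataFrame(
            {
                "pair_id": [p.pair_id for p in pairs],
                "source_id": [p.reference.source_id for p in pairs],
                "site": [p.site for p in pairs],
                "sigma_noise": [p.spec.sigma_noise for p in pairs],
                "sigma_blur": [p.spec.sigma_blur for p in pairs],
                "seed": [p.spec.seed for p in pairs],
                "crop_box": [json.dumps(p.reference.crop_box) for p in pairs],
            }
        )
        _write_csv(manifest, out / "manifest.csv")

        if config.save_images:
            img_dir = out / "images"
            img_dir.mkdir(exist_ok=True)
            done = set()
            for p in pairs:
                if p.reference.source_id not in done:
                    save_display_png(p.reference, img_dir / f"{p.reference.source_id}_ref.png")
                    done.add(p.reference.source_id)
                save_display_png(p.distorted, img_dir / f"{p.pair_id}.png")

        scores = score_pairs(pairs)
        _write_csv(scores, out / "scores.csv")

        sheet = simulate_marks(pairs, config.observer, seed=stage_seed(config, "marks"))
        subj = subjective_table(sheet)
        subj = subj.merge(
            manifest[["pair_id", "site", "source_id"]], on="pair_id", how="left"
        )
        _write_csv(subj, out / "subjective.csv")

        icc = icc_2_1(ratings_matrix(sheet))
        (out / "icc.json").write_text(
            json.dumps(
                {
                    "icc_2_1": icc.icc,
                    "ci_low": icc.ci_low,
                    "ci_high": icc.ci_high,
                    "n_items": len(subj),
                    "n_observers": config.observer.n_observers,
                },
                indent=2,
            )
        )

        records = scores.merge(subj[["pair_id", "X", "dscqs"]], on="pair_id", how="inner")
        _write_csv(records, out / "records.csv")

        summary, matrices = evaluate(
            records, METRIC_NAMES, groups=tuple(config.groups), alpha=config.alpha
        )
        _write_csv(summary, out / "summary.csv")
        for name, mat in matrices.items():
            mat.to_frame().to_csv(out / f"significance_{name}.csv")

        (out / "run_log.json").write_text(
            json.dumps(
                {
                    "package_version": __version__,
                    "python": platform.python_version(),
                    "numpy": np.__version__,
                    "base_seed": config.base_seed,
                    "stage_seeds": {s: stage_seed(config, s) for s in _STAGE_OFFSETS},
                    "n_pairs": len(pairs),
                },
                indent=2,
            )
        )
    except Exception:
        status.write_text("failed\n")
        raise
    status.write_text("ok\n")
    return out


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    """Stable column order and fixed 6-significant-digit float formatting."""
    df.to_csv(path, index=False, float_format="%.6g")


def load_records(out_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(out_dir) / "records.csv")
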