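"""The standard seeded synthetic benchmark for the splint pipeline.

Generates a balanced splint-method dataset (default 200 samples at
128 x 128 with a 5 mm calibration square), splits it 6:2:2, trains the
reduced attention U-Net (base_channels 16) with the Dice objective, and
evaluates on the held-out test split:

* segmentation quality — mIoU from micro-aggregated confusion counts;
* measurement quality — mean absolute relative error of the full
  measure pipeline against generator ground-truth areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .area import measure, measurement_error
from .nn.unet import SegModelConfig, build_model
from .synthetic import GeneratorParams, generate_dataset
from .training import TrainConfig, evaluate, load_split, train


@dataclass
class BenchmarkResult:
    miou: float                     # [0, 1]
    mean_abs_area_error_pct: float  # %
    n_test: int
    history: dict
    per_image_errors_pct: list[float]


def run_benchmark(seed: int = 0, work_dir=None, n_samples: int = 200,
                  image_size: int = 128, base_channels: int = 16,
                  depth: int = 5, epochs: int = 6, batch_size: int = 4,
                  learning_rate: float = 3e-4,
                  progress=None) -> BenchmarkResult:
    """Run the full train-and-measure benchmark; deterministic per seed."""
    import tempfile

    ctx = tempfile.TemporaryDirectory() if work_dir is None else None
    root = Path(ctx.name if ctx else work_dir)
    try:
        params = GeneratorParams(image_height=image_size, image_width=image_size,
                                 method="splint")
        manifest = generate_dataset(n_samples, params, root, seed=seed)

        config = SegModelConfig(depth=depth, base_channels=base_channels,
                                use_attention=True)
        model = build_model(config, seed=seed)
        tc = TrainConfig(epochs=epochs, batch_size=batch_size,
                         learning_rate=learning_rate, seed=seed,
                         checkpoint_path=str(root / "model.npz"))
        history = train(model, manifest, tc, dataset_root=root,
                        progress=progress)

        report = evaluate(model, manifest, dataset_root=root, split="test")

        test = load_split(manifest, root, "test")
        errors = []
        for i in range(len(test.paths)):
            img = (test.images[i].transpose(1, 2, 0) * 255.0).astype(np.uint8)
            m = measure(img, model,
                        calib_area_mm2=params.calibration_area_mm2)
            rec = measurement_error(test.true_areas[i], m.leaf_area_mm2)
            errors.append(rec.abs_error_pct)

        return BenchmarkResult(
            miou=report.miou,
            mean_abs_area_error_pct=float(np.mean(errors)),
            n_test=len(errors),
            history=history,
            per_image_errors_pct=errors,
        )
    finally:
        if ctx is not None:
            ctx.cleanup()
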