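"""Packaged synthetic-data experiments.

These routines run the full method on the packaged phantom generator and
measure how well it recovers what the generator planted: class labels,
lesion regions, impulse noise, texture orientation.  They are the package's
reproducible stand-in for benchmarking on clinical cervigram collections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gabor, network, pipeline, synthetic
from .config import PipelineConfig
from .dnrf import denoise


@dataclass
class RecoveryResult:
    accuracy: float           # held-out classification accuracy, percent
    mean_iou: float           # lesion region vs truth, cancer test images
    healthy_correct: int
    healthy_total: int
    cancer_correct: int
    cancer_total: int
    losses: list[float] = field(default_factory=list)


def synthetic_recovery(
    cfg: PipelineConfig | None = None,
    gen_seed: int = 7,
    train_seed: int = 0,
    n_train: int = 100,
    n_test: int = 30,
) -> RecoveryResult:
    """Train on n_train phantoms per class, evaluate on n_test per class.

    One generator stream (``gen_seed``) produces train + test specs in order:
    the first ``n_train`` pairs train the classifier, the remaining ``n_test``
    pairs are held out.  Returns held-out accuracy, per-class tallies and the
    mean lesion IoU over cancer-labelled test images.
    """
    cfg = cfg or PipelineConfig()
    specs = synthetic.make_specs(
        n_train + n_test, gen_seed, size=cfg.synthetic.size, noise_p=cfg.synthetic.noise_p
    )
    train_specs, test_specs = specs[: 2 * n_train], specs[2 * n_train :]

    def render(batch):
        imgs, masks, labels = [], [], []
        for s in batch:
            img, mask, label = synthetic.generate(s)
            imgs.append(img)
            masks.append(mask)
            labels.append(label)
        return imgs, masks, labels

    train_imgs, _, train_labels = render(train_specs)
    test_imgs, test_masks, test_labels = render(test_specs)

    x_train = pipeline.extract_features_batch(train_imgs, cfg)
    y_train = np.array([1.0 if lab == synthetic.CANCER else 0.0 for lab in train_labels])
    net_cfg = cfg.network_config()
    if net_cfg.seed != train_seed:
        net_cfg = network.NetworkConfig(
            input_shape=net_cfg.input_shape, ill1=net_cfg.ill1, ill2=net_cfg.ill2,
            dense_sizes=net_cfg.dense_sizes, decision_threshold=net_cfg.decision_threshold,
            seed=train_seed,
        )
    net = network.build(net_cfg)
    t = cfg.train
    hist = network.train(net, x_train, y_train, epochs=t.epochs, lr=t.lr,
                         batch_size=t.batch_size, seed=train_seed)

    h_ok = h_tot = c_ok = c_tot = 0
    ious = []
    for img, mask, label in zip(test_imgs, test_masks, test_labels):
        products = pipeline.process_image(img, cfg)
        pred = net.forward(products.features)
        if label == synthetic.CANCER:
            c_tot += 1
            c_ok += pred.value == synthetic.CANCER
            seg = pipeline.segment_products(products, cfg)
            ious.append(pipeline.iou(seg.region, mask))
        else:
            h_tot += 1
            h_ok += pred.value == synthetic.HEALTHY
    return RecoveryResult(
        accuracy=100.0 * (h_ok + c_ok) / (h_tot + c_tot),
        mean_iou=float(np.mean(ious)),
        healthy_correct=h_ok,
        healthy_total=h_tot,
        cancer_correct=c_ok,
        cancer_total=c_tot,
        losses=hist.losses,
    )


def dnrf_efficacy(
    seed: int = 0,
    size: tuple[int, int] = (128, 128),
    noise_p: float = 0.05,
    threshold: float = 20.0,
) -> dict:
    """MAE against the clean image before vs after denoising a healthy
    phantom carrying impulse noise."""
    base = synthetic.make_specs(1, seed, size=size, noise_p=0.0)[0]
    clean, _, _ = synthetic.generate(base)
    noisy_spec = synthetic.SyntheticSpec(
        size=base.size, label=base.label, lesion=base.lesion, texture=base.texture,
        background=base.background, noise_p=noise_p, seed=base.seed,
    )
    noisy, _, _ = synthetic.generate(noisy_spec)
    filtered, mask = denoise(noisy, threshold=threshold)
    c = clean.astype(np.float64)
    return {
        "mae_noisy": float(np.abs(noisy - c).mean()),
        "mae_filtered": float(np.abs(filtered - c).mean()),
        "detected_fraction": float(mask.mean()),
    }


def orientation_recovery(
    orientation_deg: float = 15.0,
    size: tuple[int, int] = (128, 128),
    cfg: PipelineConfig | None = None,
    border: int = 16,
) -> dict:
    """Sweep a full-frame grating and report the modal winning orientation
    over the interior, its error, and the modal frequency."""
    cfg = cfg or PipelineConfig()
    h, w = size
    yy, xx = np.mgrid[:h, :w].astype(np.float64)
    th = np.deg2rad(orientation_deg)
    img = 128.0 + 60.0 * np.sin(2.0 * np.pi * (xx * np.cos(th) + yy * np.sin(th)) / cfg.gabor.wavelength)
    g = gabor.gci(img, cfg.gabor)
    interior = g.winning_theta[border:-border, border:-border].ravel()
    vals, counts = np.unique(interior, return_counts=True)
    mode = float(vals[counts.argmax()])
    err = abs(mode - orientation_deg)
    err = min(err, 180.0 - err)  # orientation is mod 180
    return {
        "mode_theta_deg": mode,
        "error_deg": float(err),
        "mode_fraction": float(counts.max() / interior.size),
    }
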