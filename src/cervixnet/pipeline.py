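"""End-to-end orchestration: denoise -> Gabor fusion -> features ->
classification -> (cancer only) segmentation -> evaluation.

Stage products are deterministic functions of the input image and the
configuration, and the texture-energy map is carried as float32, so running
the stages one at a time through the CLI (with float-TIFF intermediates)
reproduces the in-memory end-to-end results bit for bit.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dnrf, gabor, metrics, network, segmentation
from .config import PipelineConfig
from .core import load_image, load_mask
from .features import FeatureMatrix, compute_features
from .network import CANCER, ClassLabel, Network

log = logging.getLogger("cervixnet")


@dataclass
class StageProducts:
    filtered: np.ndarray      # denoised uint8 image
    noise_mask: np.ndarray    # {0,1} detected impulse pixels
    energy: np.ndarray        # float32 GCI in matched-amplitude units (0-255)
    features: FeatureMatrix


def texture_energy(filtered: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Fused Gabor texture-energy map in equivalent-amplitude units."""
    g = gabor.gci(filtered, cfg.gabor)
    return gabor.equivalent_amplitude(g.pixels, cfg.gabor)


def feature_matrix(energy: np.ndarray, cfg: PipelineConfig) -> FeatureMatrix:
    f = cfg.features
    return compute_features(
        energy,
        grid=f.grid,
        ltp_t=f.ltp_t,
        glcm_levels=f.glcm_levels,
        glcm_offset=f.glcm_offset,
        lbp_rule=f.lbp_rule,
        nsct_dirs=f.nsct_dirs,
    )


def process_image(img: np.ndarray, cfg: PipelineConfig) -> StageProducts:
    """All pre-classification stages on one image."""
    d = cfg.dnrf
    filtered, mask = dnrf.denoise(
        img, threshold=d.threshold, window=d.window, avg_window=d.avg_window, hm_mode=d.hm_mode
    )
    energy = texture_energy(filtered, cfg)
    return StageProducts(
        filtered=filtered,
        noise_mask=mask,
        energy=energy,
        features=feature_matrix(energy, cfg),
    )


def segment_products(products: StageProducts, cfg: PipelineConfig) -> segmentation.SegmentationResult:
    source = cfg.segmentation.source
    img = products.energy if source == "gci" else products.filtered
    return segmentation.segment_image(img, se=cfg.segmentation.se, source=source)


def _load_manifest(manifest: str | os.PathLike | pd.DataFrame) -> pd.DataFrame:
    if isinstance(manifest, pd.DataFrame):
        df = manifest
    else:
        if not os.path.exists(manifest):
            raise FileNotFoundError(f"manifest not found: {manifest}")
        df = pd.read_csv(manifest)
    if df.empty:
        raise ValueError("manifest is empty")
    missing = [p for p in df["path"] if not os.path.exists(p)]
    if missing:
        raise FileNotFoundError(f"missing image files: {missing}")
    return df


def extract_features_batch(images: list[np.ndarray], cfg: PipelineConfig) -> np.ndarray:
    """(B, M, N) stack of feature matrices."""
    out = []
    for i, img in enumerate(images):
        out.append(process_image(img, cfg).features.values)
        log.debug("features %d/%d", i + 1, len(images))
    return np.stack(out)


def run_train(
    cfg: PipelineConfig,
    manifest: str | os.PathLike | pd.DataFrame,
    checkpoint: str | os.PathLike | None = None,
) -> tuple[Network, network.TrainHistory]:
    """Train CervixNet on a manifest of labelled images."""
    df = _load_manifest(manifest)
    labels = np.array([1.0 if lab == CANCER else 0.0 for lab in df["label"]])
    if len(np.unique(labels)) < 2:
        raise ValueError("training manifest must contain both classes")
    images = [load_image(p) for p in df["path"]]
    log.info("extracting features for %d training images", len(images))
    fms = extract_features_batch(images, cfg)
    net = network.build(cfg.network_config())
    t = cfg.train
    history = network.train(
        net, fms, labels, epochs=t.epochs, lr=t.lr, batch_size=t.batch_size, seed=t.seed
    )
    log.info("training done: first-epoch loss %.4f, last %.4f",
             history.losses[0] if history.losses else float("nan"),
             history.losses[-1] if history.losses else float("nan"))
    if checkpoint is not None:
        net.save(checkpoint)
    return net, history


def classify_image(net: Network, img: np.ndarray, cfg: PipelineConfig) -> ClassLabel:
    return net.forward(process_image(img, cfg).features)


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred) > 0
    truth = np.asarray(truth) > 0
    union = np.count_nonzero(pred | truth)
    if union == 0:
        return 1.0
    return float(np.count_nonzero(pred & truth) / union)


def run_test(
    cfg: PipelineConfig,
    net: Network,
    manifest: str | os.PathLike | pd.DataFrame,
    segment: bool = True,
) -> pd.DataFrame:
    """Classify every manifest image; segment the cancer-labelled ones and,
    where a truth mask exists, score the segmentation per image.

    Columns: path, true label (if present), predicted label, score, and for
    segmented images with truth masks: iou, cps, cpsp, cpa.
    """
    df = _load_manifest(manifest)
    rows = []
    for rec in df.to_dict("records"):
        img = load_image(rec["path"])
        products = process_image(img, cfg)
        label = net.forward(products.features)
        row: dict = {
            "path": rec["path"],
            "label": rec.get("label"),
            "predicted": label.value,
            "score": label.score,
        }
        # conditional flow: only cancer-classified images are segmented
        if segment and label.value == CANCER:
            seg = segment_products(products, cfg)
            row["segmented"] = True
            mask_path = rec.get("mask_path")
            if isinstance(mask_path, str) and os.path.exists(mask_path):
                truth = load_mask(mask_path)
                row["iou"] = iou(seg.region, truth)
                if truth.any():
                    pm = metrics.pixel_metrics(metrics.confusion(seg.region, truth))
                    row.update({"cps": pm.cps, "cpsp": pm.cpsp, "cpa": pm.cpa})
        else:
            row["segmented"] = False
        rows.append(row)
    return pd.DataFrame(rows)
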