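"""Synthetic cohorts for end-to-end exercise of the pipeline.

The generator encodes the MIL premise that only a minority of "key" patches
carry the MSI signal: an MSI slide's bag of patch likelihoods is a mixture of
a key-patch component concentrated near 1 and a background component shared
with MSS slides.  Three generators are provided:

* likelihood mode — bags of patch likelihoods drawn from Beta mixtures;
* image mode — mosaics of textured tiles (dense dark blobs on key tiles)
  with an ImageScope-style ROI annotation per slide;
* omics — mutation and expression tables whose MSI/MSS contrasts mirror the
  known associations (higher TMB, INDEL load, mismatch-repair deficiency,
  and cytolytic/T-effector expression in MSI).

A domain-shifted second cohort is modeled by ``shift_strength``: in
likelihood space both Beta component means are pulled toward 0.5 by
``0.15 * shift_strength``; in image space a color cast is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import MSI, MSS, SlideRecord
from .patch_mil import PatchStore
from .roi_tiling import ROIAnnotation, write_annotation_xml

MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")
CYT_GENES = ("GZMA", "PRF1")
CD8_TEFF_GENES = ("CD8A", "IFNG", "GZMA", "PRF1", "CXCL9", "CXCL10", "TBX21", "GZMB")
_OTHER_GENES = ("TP53", "APC", "KRAS", "PIK3CA", "TTN", "MUC16", "SYNE1", "FAT4")


@dataclass
class SyntheticCohortConfig:
    """Parameters of the synthetic study conditions.

    Defaults follow the modeled setting: MSI prevalence ~0.17 (71/429-like
    class balance), bags of 20-400 patches, background likelihoods
    Beta(2,8) (mean 0.2), key-patch likelihoods Beta(8,2) (mean 0.8) at
    key fraction 0.3, and a likelihood-space domain shift that pulls both
    component means toward 0.5 by 0.15 per unit of shift strength.
    """

    n_slides: int = 300
    msi_prevalence: float = 0.17
    patches_per_slide: tuple[int, int] = (20, 400)
    mss_beta: tuple[float, float] = (2.0, 8.0)
    msi_key_beta: tuple[float, float] = (8.0, 2.0)
    key_patch_fraction: float = 0.3
    shift_strength: float = 0.0
    mode: str = "likelihood"
    tile_size: int = 64
    tiles_per_side: int = 4  # image-mode mosaic is tiles_per_side^2 tiles
    blob_rate_key: float = 25.0
    blob_rate_background: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.msi_prevalence <= 1:
            raise ValueError("msi_prevalence must be in [0,1]")
        if not 0 < self.key_patch_fraction <= 1:
            raise ValueError("key_patch_fraction must be in (0,1]")
        if min(self.mss_beta + self.msi_key_beta) <= 0:
            raise ValueError("beta parameters must be positive")
        if self.shift_strength < 0:
            raise ValueError("shift_strength must be >= 0")
        if self.mode not in ("likelihood", "image"):
            raise ValueError("mode must be 'likelihood' or 'image'")


def _shifted_beta(params: tuple[float, float], shift: float) -> tuple[float, float]:
    """Pull a Beta distribution's mean toward 0.5 by 0.15*shift, keeping a+b."""
    a, b = params
    kappa = a + b
    mean = a / kappa
    delta = min(0.15 * shift, abs(0.5 - mean))
    mean = mean + np.sign(0.5 - mean) * delta
    return mean * kappa, (1 - mean) * kappa


def simulate_likelihood_cohort(
    cfg: SyntheticCohortConfig,
) -> tuple[list[SlideRecord], pd.DataFrame]:
    """Draw slide labels and per-patch likelihood bags.

    MSS bags ~ Beta(mss_beta); MSI bags are the key-patch mixture
    pi * Beta(msi_key_beta) + (1-pi) * Beta(mss_beta).  Deterministic per seed.
    """
    if cfg.mode != "likelihood":
        raise ValueError("config mode must be 'likelihood'")
    rng = np.random.default_rng(cfg.seed)
    mss_ab = _shifted_beta(cfg.mss_beta, cfg.shift_strength)
    key_ab = _shifted_beta(cfg.msi_key_beta, cfg.shift_strength)

    records, rows = [], []
    for i in range(cfg.n_slides):
        sid = f"SYN{i:04d}"
        label = MSI if rng.random() < cfg.msi_prevalence else MSS
        n = int(rng.integers(cfg.patches_per_slide[0], cfg.patches_per_slide[1] + 1))
        if label == MSI:
            is_key = rng.random(n) < cfg.key_patch_fraction
            lik = np.where(
                is_key,
                rng.beta(*key_ab, size=n),
                rng.beta(*mss_ab, size=n),
            )
        else:
            lik = rng.beta(*mss_ab, size=n)
        records.append(
            SlideRecord(slide_id=sid, cohort="synthetic", ms_label=label, n_patches=n)
        )
        for j, p in enumerate(lik):
            rows.append((sid, j, 0, float(p)))
    table = pd.DataFrame(rows, columns=["slide_id", "grid_x", "grid_y", "likelihood"])
    return records, table


def _render_tile(rng: np.random.Generator, size: int, blob_rate: float,
                 color_cast: float = 0.0) -> np.ndarray:
    """One tile: pinkish Gaussian-noise texture with Poisson-count dark blobs."""
    base = np.array([220.0, 180.0, 200.0])  # eosin-like background
    img = base + rng.normal(0, 12, size=(size, size, 3))
    n_blobs = rng.poisson(blob_rate)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0, size, 2)
        r = rng.uniform(1.5, 3.5)
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 < r**2
        img[mask] *= 0.35  # dark hematoxylin-like blob
    if color_cast:
        img[..., 0] += 25 * color_cast  # FFPE-like red/hue offset
        img[..., 2] -= 15 * color_cast
    return np.clip(img, 0, 255).astype(np.uint8)


def simulate_image_cohort(
    cfg: SyntheticCohortConfig, out_dir: str | Path | None = None
) -> tuple[list[SlideRecord], PatchStore, dict[str, ROIAnnotation]]:
    """Generate mosaic slides of textured tiles plus ROI annotation polygons.

    MSI slides contain a fraction ``key_patch_fraction`` of key tiles with
    dense dark blobs (Poisson rate ``blob_rate_key``); all other tiles use
    the sparse background rate.  The ROI polygon covers a random
    sub-rectangle of the mosaic (in pixel coordinates).  If ``out_dir`` is
    given, tiles are written as PNGs and annotations as ImageScope XML.
    """
    if cfg.mode != "image":
        raise ValueError("config mode must be 'image'")
    rng = np.random.default_rng(cfg.seed)
    records, store, annotations = [], PatchStore(), {}
    g = cfg.tiles_per_side
    for i in range(cfg.n_slides):
        sid = f"IMG{i:04d}"
        label = MSI if rng.random() < cfg.msi_prevalence else MSS
        is_key = np.zeros((g, g), dtype=bool)
        if label == MSI:
            is_key = rng.random((g, g)) < cfg.key_patch_fraction
        for gy in range(g):
            for gx in range(g):
                rate = cfg.blob_rate_key if is_key[gy, gx] else cfg.blob_rate_background
                tile = _render_tile(
                    rng, cfg.tile_size, rate, color_cast=cfg.shift_strength
                )
                store.add(sid, gx, gy, tile)
        extent = g * cfg.tile_size
        x0, y0 = rng.uniform(0, extent / 4, 2)
        x1 = rng.uniform(3 * extent / 4, extent)
        y1 = rng.uniform(3 * extent / 4, extent)
        ring = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
        annotations[sid] = ROIAnnotation(slide_id=sid, polygons=[ring])
        records.append(
            SlideRecord(slide_id=sid, cohort="synthetic-image", ms_label=label,
                        n_patches=g * g)
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "tiles").mkdir(parents=True, exist_ok=True)
        store.write_directory(out_dir / "tiles")
        (out_dir / "annotations").mkdir(exist_ok=True)
        for sid, roi in annotations.items():
            write_annotation_xml(roi, out_dir / "annotations" / f"{sid}.xml")
    return records, store, annotations


def simulate_omics(
    slides: list[SlideRecord], seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mutation and expression tables with MSI-linked contrasts.

    Per sample the nonsynonymous mutation count is logNormal(mu=3.5, sigma=0.3)
    for MSI versus logNormal(1.5, 0.3) for MSS; INDELs are a Binomial thinning
    of that count (rate 0.25 MSI vs 0.08 MSS); a mismatch-repair gene receives
    a nonsynonymous hit with probability 0.8 (MSI) vs 0.05 (MSS).  Expression
    of the cytolytic and CD8 T-effector genes is shifted +2 log2-fold in MSI
    with unit Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    mut_rows = []
    expr_cols = {}
    genes = list(dict.fromkeys(CD8_TEFF_GENES + _OTHER_GENES))
    for r in slides:
        if r.ms_label is None:
            raise ValueError(f"slide {r.slide_id} is unlabeled")
        msi = r.ms_label == MSI
        mu = 3.5 if msi else 1.5
        n_mut = max(int(round(rng.lognormal(mu, 0.3))), 1)
        n_indel = rng.binomial(n_mut, 0.25 if msi else 0.08)
        n_snv = n_mut - n_indel
        for _ in range(n_snv):
            gene = _OTHER_GENES[rng.integers(len(_OTHER_GENES))]
            vclass = "missense" if rng.random() < 0.8 else "nonsense"
            mut_rows.append((r.slide_id, gene, vclass))
        for _ in range(n_indel):
            gene = _OTHER_GENES[rng.integers(len(_OTHER_GENES))]
            mut_rows.append((r.slide_id, gene, "INS" if rng.random() < 0.5 else "DEL"))
        # a few synonymous rows that all downstream analyses must ignore
        for _ in range(rng.poisson(3)):
            gene = _OTHER_GENES[rng.integers(len(_OTHER_GENES))]
            mut_rows.append((r.slide_id, gene, "synonymous"))
        if rng.random() < (0.8 if msi else 0.05):
            gene = MMR_GENES[rng.integers(len(MMR_GENES))]
            mut_rows.append((r.slide_id, gene, "frameshift"))

        shift = 2.0 if msi else 0.0
        log2x = rng.normal(3.0 + shift, 1.0, size=len(CD8_TEFF_GENES))
        other = rng.normal(3.0, 1.0, size=len(genes) - len(CD8_TEFF_GENES))
        vals = np.concatenate([log2x, other])
        expr_cols[r.slide_id] = np.maximum(2.0**vals - 1, 0.0)

    mutations = pd.DataFrame(mut_rows, columns=["sample_id", "gene", "variant_class"])
    expression = pd.DataFrame(expr_cols, index=genes)
    expression.index.name = "gene"
    return mutations, expression
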