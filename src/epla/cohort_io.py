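"""Slide manifests, microsatellite-status labeling rules, and cohort partitioning.

A cohort is a list of :class:`SlideRecord` objects, one per whole-slide image.
The MS label can be derived from either of two assays: an MSIsensor score
(tumor/normal sequencing; score >= 10 defines MSI) or a five-locus PCR panel
(instability at >= 2 of 5 loci defines MSI-high; MSI-low is pooled with MSS).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MSI = "MSI"
MSS = "MSS"

#: Default MSIsensor threshold: score >= 10 is called MSI.
MSISENSOR_THRESHOLD = 10.0
#: Default locus rule: instability at >= 2 of the 5 panel loci is called MSI.
MIN_UNSTABLE_LOCI = 2


@dataclass
class SlideRecord:
    """One slide with its cohort, label sources, and split assignment."""

    slide_id: str
    cohort: str = ""
    msisensor_score: float | None = None
    unstable_loci: int | None = None
    ms_label: str | None = None
    n_patches: int = 0
    split: str = "unassigned"
    image_dir: str | None = None
    annotation_xml: str | None = None

    def replace(self, **kw) -> "SlideRecord":
        return dataclasses.replace(self, **kw)


@dataclass
class CohortPartition:
    """Disjoint train/test slide-id sets from a stratified split."""

    train_ids: set[str]
    test_ids: set[str]
    ratio: float
    seed: int

    def split_of(self, slide_id: str) -> str:
        if slide_id in self.train_ids:
            return "train"
        if slide_id in self.test_ids:
            return "test"
        return "unassigned"

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, "train") for s in sorted(self.train_ids)]
        rows += [(s, "test") for s in sorted(self.test_ids)]
        return pd.DataFrame(rows, columns=["slide_id", "split"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


_LABEL_SOURCE_COLUMNS = ("msisensor_score", "unstable_loci", "ms_label")


def load_manifest(path: str | Path, dialect: str = "tsv") -> list[SlideRecord]:
    """Read a slide manifest (TSV or CSV) into records.

    The header must include ``slide_id`` and at least one label source column
    (``msisensor_score``, ``unstable_loci``, or a precomputed ``ms_label``).
    Missing optional cells are left absent (None).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, dtype={"slide_id": str})
    if "slide_id" not in df.columns:
        raise ValueError("manifest lacks required column 'slide_id'")
    if not any(c in df.columns for c in _LABEL_SOURCE_COLUMNS):
        raise ValueError(
            "manifest lacks a label source column "
            f"(one of {', '.join(_LABEL_SOURCE_COLUMNS)})"
        )
    dup = df["slide_id"][df["slide_id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate slide_id(s) in manifest: {', '.join(dup)}")

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(key, cast):
            v = d.get(key)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return cast(v)

        records.append(
            SlideRecord(
                slide_id=str(d["slide_id"]),
                cohort=str(opt("cohort", str) or ""),
                msisensor_score=opt("msisensor_score", float),
                unstable_loci=opt("unstable_loci", int),
                ms_label=opt("ms_label", str),
                image_dir=opt("image_dir", str),
                annotation_xml=opt("annotation_xml", str),
            )
        )
    return records


def label_from_msisensor(
    records: list[SlideRecord], threshold: float = MSISENSOR_THRESHOLD
) -> list[SlideRecord]:
    """Assign MS labels from MSIsensor scores: MSI iff score >= threshold."""
    out = []
    for r in records:
        if r.msisensor_score is None:
            raise ValueError(f"slide {r.slide_id}: msisensor_score absent")
        out.append(r.replace(ms_label=MSI if r.msisensor_score >= threshold else MSS))
    return out


def label_from_loci(
    records: list[SlideRecord], min_unstable: int = MIN_UNSTABLE_LOCI
) -> list[SlideRecord]:
    """Assign MS labels from the 5-locus panel: MSI iff unstable loci >= min_unstable.

    MSI-low (one unstable locus) is pooled into the MSS class.
    """
    out = []
    for r in records:
        if r.unstable_loci is None:
            raise ValueError(f"slide {r.slide_id}: unstable_loci absent")
        if not 0 <= r.unstable_loci <= 5:
            raise ValueError(
                f"slide {r.slide_id}: unstable_loci {r.unstable_loci} outside 0-5"
            )
        out.append(r.replace(ms_label=MSI if r.unstable_loci >= min_unstable else MSS))
    return out


def stratified_split(
    records: list[SlideRecord], train_fraction: float = 0.7, seed: int = 0
) -> CohortPartition:
    """Stratified train/test split preserving class proportions.

    Per class, the train count is ``train_fraction * n`` rounded to the nearest
    integer with ties toward train; membership is a seeded permutation, so the
    partition is deterministic given the seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0,1)")
    by_class: dict[str, list[str]] = {}
    for r in records:
        if r.ms_label is None:
            raise ValueError(f"slide {r.slide_id} is unlabeled")
        by_class.setdefault(r.ms_label, []).append(r.slide_id)

    rng = np.random.default_rng(seed)
    train_ids: set[str] = set()
    test_ids: set[str] = set()
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        if len(ids) < 2:
            raise ValueError(f"class {label} has fewer than 2 slides")
        n_train = int(np.floor(train_fraction * len(ids) + 0.5))  # ties toward train
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train_ids.update(ids[i] for i in perm[:n_train])
        test_ids.update(ids[i] for i in perm[n_train:])
    return CohortPartition(train_ids, test_ids, train_fraction, seed)


def apply_partition(
    records: list[SlideRecord], part: CohortPartition
) -> list[SlideRecord]:
    return [r.replace(split=part.split_of(r.slide_id)) for r in records]


def labels_series(records: list[SlideRecord]) -> pd.Series:
    """slide_id-indexed 0/1 series (MSI = 1)."""
    return pd.Series(
        {r.slide_id: 1 if r.ms_label == MSI else 0 for r in records}, name="label"
    )


def write_manifest(records: list[SlideRecord], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df.to_csv(path, sep="\t", index=False)
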