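"""DNA-repair pathway status, deleterious-variant filtering and mutation burden.

Samples are screened for deleterious somatic variants in homologous
recombination (HR) genes, mismatch repair (MMR) genes and POLE.  A
variant counts as deleterious when it is a nonsense, splice or indel
change, or a missense change predicted damaging by SIFT (< 0.05) or
CADD (> 20).  Tumor mutation burden (TMB) is a per-sample count of MAF
rows, and the cohort is split at the median burden.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import SomaticVariant

logger = logging.getLogger(__name__)

__all__ = [
    "HR_GENES",
    "MMR_GENES",
    "POLE_GENES",
    "ANTIGEN_PRESENTATION_GENES",
    "WNT_PANEL",
    "PathwayGeneLists",
    "RepairStatus",
    "is_deleterious",
    "classify_repair",
    "mutation_burden",
    "median_split",
]

#: Homologous recombination genes screened for deleterious variants.
HR_GENES = (
    "ATR", "ATM", "CHEK1", "CHEK2", "BRCA1", "BRCA2", "BAP1", "BARD1",
    "FANCD2", "FANCE", "FANCC", "FANCA", "RAD50", "RAD51", "PALB2",
)

#: Mismatch repair genes screened for deleterious variants.
MMR_GENES = (
    "MLH1", "MLH3", "MSH2", "MSH3", "MSH4", "MSH5", "MSH6", "PMS1",
    "PMS2", "PMS2L3", "PCNA", "EXO1", "POLD1", "RFC1", "RFC2", "RFC3",
    "RFC4", "RFC5",
)

POLE_GENES = ("POLE",)

#: Antigen-presentation machinery genes (HLA class I, B2M, TAP2, LMP-7).
ANTIGEN_PRESENTATION_GENES = ("HLA-A", "HLA-B", "HLA-C", "B2M", "TAP2", "PSMB8")

#: Immunosuppressive TGF-β / Wnt panel compared across immunophenotype groups.
WNT_PANEL = (
    "APC", "CTNNB1", "WNT1", "WNT2", "WNT3A", "WNT5A", "WNT7A",
    "TGFB1", "TGFB2", "TGFB3", "VEGFA",
)


@dataclass(frozen=True)
class PathwayGeneLists:
    """Gene lists defining the screened DNA-repair pathways."""

    hr: tuple[str, ...] = HR_GENES
    mmr: tuple[str, ...] = MMR_GENES
    pole: tuple[str, ...] = POLE_GENES
    antigen_presentation: tuple[str, ...] = ANTIGEN_PRESENTATION_GENES
    wnt_panel: tuple[str, ...] = WNT_PANEL


DEFAULT_LISTS = PathwayGeneLists()

#: Variant classes that are deleterious regardless of prediction scores.
_ALWAYS_DELETERIOUS = {"nonsense", "frameshift-indel", "inframe-indel"}


@dataclass(frozen=True)
class RepairStatus:
    """Per-sample DNA-repair pathway flags and mutation burden."""

    sample_id: str
    hr_variant: bool
    mmr_variant: bool
    pole_variant: bool
    affected_gene_count: int
    tmb: int

    @property
    def any_variant(self) -> bool:
        return self.hr_variant or self.mmr_variant or self.pole_variant


def is_deleterious(
    variant: SomaticVariant,
    sift_cut: float = 0.05,
    cadd_cut: float = 20.0,
) -> bool:
    """Decide whether a variant is predicted deleterious.

    Nonsense and indel changes always qualify.  Splice changes qualify
    when, given an intron offset, the variant lies on the intronic side
    within 2 bp of the junction; without an offset the MAF splice
    classification is trusted.  Missense changes qualify when
    SIFT < ``sift_cut`` or CADD > ``cadd_cut`` (strict inequalities);
    a missense with neither score available is treated as benign.
    """
    cls = variant.classification
    if cls in _ALWAYS_DELETERIOUS:
        return True
    if cls == "splice":
        if variant.intron_offset is None:
            return True
        return variant.intron_offset < 0 and abs(variant.intron_offset) <= 2
    if cls == "missense":
        if variant.sift is not None and variant.sift < sift_cut:
            return True
        if variant.cadd is not None and variant.cadd > cadd_cut:
            return True
    return False


def _group_by_sample(variants: Iterable[SomaticVariant]) -> dict[str, list[SomaticVariant]]:
    grouped: dict[str, list[SomaticVariant]] = defaultdict(list)
    for v in variants:
        grouped[v.sample_id].append(v)
    return grouped


def classify_repair(
    variants: Iterable[SomaticVariant],
    lists: PathwayGeneLists = DEFAULT_LISTS,
    sift_cut: float = 0.05,
    cadd_cut: float = 20.0,
    samples: Sequence[str] | None = None,
    tmb_mode: str = "all",
) -> dict[str, RepairStatus]:
    """Assign HR/MMR/POLE status and TMB per sample.

    A pathway flag is set iff the sample carries at least one
    deleterious variant in a listed gene; ``affected_gene_count`` counts
    distinct affected genes across the three lists.  ``samples`` may add
    identifiers absent from the MAF (e.g. present only in the expression
    matrix); they receive an all-false status with TMB 0 and stay in the
    cohort.
    """
    grouped = _group_by_sample(variants)
    all_samples = list(grouped)
    if samples is not None:
        known = set(all_samples)
        for s in samples:
            if s not in known:
                all_samples.append(s)
    hr, mmr, pole = set(lists.hr), set(lists.mmr), set(lists.pole)

    burdens = mutation_burden(grouped, mode=tmb_mode, samples=all_samples)
    out: dict[str, RepairStatus] = {}
    for sample in all_samples:
        affected: set[str] = set()
        hr_flag = mmr_flag = pole_flag = False
        for v in grouped.get(sample, ()):
            if v.gene not in hr and v.gene not in mmr and v.gene not in pole:
                continue
            if not is_deleterious(v, sift_cut=sift_cut, cadd_cut=cadd_cut):
                continue
            affected.add(v.gene)
            hr_flag = hr_flag or v.gene in hr
            mmr_flag = mmr_flag or v.gene in mmr
            pole_flag = pole_flag or v.gene in pole
        out[sample] = RepairStatus(
            sample_id=sample,
            hr_variant=hr_flag,
            mmr_variant=mmr_flag,
            pole_variant=pole_flag,
            affected_gene_count=len(affected),
            tmb=burdens[sample],
        )
    return out


def mutation_burden(
    variants: Iterable[SomaticVariant] | Mapping[str, list[SomaticVariant]],
    mode: str = "all",
    samples: Sequence[str] | None = None,
) -> dict[str, int]:
    """Count mutations per sample.

    ``mode="all"`` counts every MAF row; ``"nonsynonymous"`` excludes
    silent and "other" classifications.  Samples listed in ``samples``
    but absent from the MAF get a count of 0 with a warning.
    """
    if mode not in {"all", "nonsynonymous"}:
        raise ValueError(f"unknown TMB mode {mode!r}")
    grouped = variants if isinstance(variants, Mapping) else _group_by_sample(variants)
    counts: dict[str, int] = {}
    for sample, sample_variants in grouped.items():
        if mode == "all":
            counts[sample] = len(sample_variants)
        else:
            counts[sample] = sum(v.classification not in {"silent", "other"} for v in sample_variants)
    if samples is not None:
        for s in samples:
            if s not in counts:
                logger.warning("sample %s absent from MAF; mutation burden set to 0", s)
                counts[s] = 0
    return counts


def median_split(values: Mapping[str, float]) -> tuple[dict[str, str], float]:
    """Split samples into "high"/"low" at the median value.

    A sample is "high" iff its value is strictly greater than the
    median; ties at the median go to "low".
    """
    if not values:
        raise ValueError("median_split requires at least one value")
    median = float(np.median(list(values.values())))
    labels = {s: ("high" if v > median else "low") for s, v in values.items()}
    if all(label == "low" for label in labels.values()):
        logger.warning("median split produced no high samples (all values <= median)")
    return labels, median


def status_frame(statuses: Mapping[str, RepairStatus]) -> pd.DataFrame:
    """Tabulate per-sample repair status (one row per sample)."""
    rows = [
        {
            "sample_id": s.sample_id,
            "hr_variant": s.hr_variant,
            "mmr_variant": s.mmr_variant,
            "pole_variant": s.pole_variant,
            "any_variant": s.any_variant,
            "affected_gene_count": s.affected_gene_count,
            "tmb": s.tmb,
        }
        for s in statuses.values()
    ]
    return pd.DataFrame(rows).set_index("sample_id")
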