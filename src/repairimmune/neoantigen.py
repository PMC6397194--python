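"""Neoantigen calling from missense variants.

For every missense variant the 9-mer peptide windows covering the
mutated residue are enumerated in mutant/wild-type pairs.  A mutant
peptide is called a neoantigen on a given HLA allele when it binds
strongly (IC50 < 500 nM), its wild-type counterpart binds weakly
(IC50 > 500 nM) on the same allele, and the variant's gene is expressed
(> 0) in the sample.  Per-sample burden is the number of distinct
passing mutant peptides (or of passing peptide–allele pairs).

Binding affinities are inputs (an :class:`~repairimmune.cohort_io.AffinityTable`
or any ``(peptide, allele) -> nM`` callable); :class:`ToyPredictor` is a
deterministic position-weight stand-in used by the synthetic cohorts and
the test suite.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .cohort_io import AffinityTable, SomaticVariant

__all__ = [
    "PeptidePair",
    "NeoantigenCall",
    "mutant_windows",
    "pairs_for_variant",
    "call_neoantigens",
    "neoantigen_burden",
    "ToyPredictor",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class PeptidePair:
    """A mutant/wild-type peptide window around a missense site."""

    sample_id: str
    gene: str
    protein_pos: int
    window_start: int  # 1-based start of the window in the protein
    wt_peptide: str
    mut_peptide: str

    def __post_init__(self) -> None:
        if len(self.wt_peptide) != len(self.mut_peptide):
            raise ValueError("wild-type and mutant peptides must have equal length")
        diffs = sum(a != b for a, b in zip(self.wt_peptide, self.mut_peptide))
        if diffs != 1:
            raise ValueError(f"peptide pair must differ at exactly one position (got {diffs})")


@dataclass(frozen=True)
class NeoantigenCall:
    pair: PeptidePair
    allele: str
    mut_ic50: float
    wt_ic50: float
    expressed: bool
    is_neoantigen: bool


def mutant_windows(
    protein: str,
    pos: int,
    ref_aa: str,
    alt_aa: str,
    sample_id: str = "",
    gene: str = "",
    k: int = 9,
) -> list[PeptidePair]:
    """Enumerate all k-mer windows containing a mutated residue.

    Windows start at every 1-based index ``s`` with
    ``max(1, pos-k+1) <= s <= min(pos, len(protein)-k+1)``, i.e. every
    k-mer whose span covers ``pos``, clipped to the protein ends.

    Raises
    ------
    ValueError
        If ``pos`` is out of range, the protein is shorter than ``k``,
        or the protein residue at ``pos`` does not match ``ref_aa``.
    """
    length = len(protein)
    if not 1 <= pos <= length:
        raise ValueError(f"position {pos} outside protein of length {length} ({gene})")
    if k > length:
        raise ValueError(f"protein of length {length} shorter than window size {k} ({gene})")
    if protein[pos - 1] != ref_aa:
        raise ValueError(
            f"reference residue mismatch for {gene or 'protein'} position {pos}: "
            f"expected {ref_aa}, protein has {protein[pos - 1]}"
        )
    mutant = protein[: pos - 1] + alt_aa + protein[pos:]
    pairs = []
    for start in range(max(1, pos - k + 1), min(pos, length - k + 1) + 1):
        pairs.append(
            PeptidePair(
                sample_id=sample_id,
                gene=gene,
                protein_pos=pos,
                window_start=start,
                wt_peptide=protein[start - 1 : start - 1 + k],
                mut_peptide=mutant[start - 1 : start - 1 + k],
            )
        )
    return pairs


def pairs_for_variant(
    variant: SomaticVariant,
    proteins: Mapping[str, str],
    k: int = 9,
) -> list[PeptidePair]:
    """Windows for one missense variant given its protein sequence.

    Non-missense variants, or variants without a protein change or a
    protein sequence, yield no pairs (frameshift neo-ORFs are out of
    scope).
    """
    if variant.classification != "missense" or variant.protein_pos is None:
        return []
    protein = proteins.get(variant.gene)
    if protein is None:
        return []
    return mutant_windows(
        protein,
        variant.protein_pos,
        variant.ref_aa,
        variant.alt_aa,
        sample_id=variant.sample_id,
        gene=variant.gene,
        k=k,
    )


AffinitySource = AffinityTable | Callable[[str, str], float]


def _ic50(affinity: AffinitySource, peptide: str, allele: str) -> float:
    if isinstance(affinity, AffinityTable):
        return affinity.lookup(peptide, allele)
    return affinity(peptide, allele)


def call_neoantigens(
    pairs: Iterable[PeptidePair],
    alleles: Sequence[str],
    affinity: AffinitySource,
    expression: Mapping[str, float],
    mut_cut: float = 500.0,
    wt_cut: float = 500.0,
) -> list[NeoantigenCall]:
    """Apply the binding/expression filter to peptide pairs.

    One call is produced per pair × allele.  A call passes iff
    ``mut_ic50 < mut_cut`` and ``wt_ic50 > wt_cut`` (strict, so an IC50
    of exactly 500 nM fails both) and the variant's gene has expression
    > 0 in the sample.  Mutant and wild-type affinities are compared on
    the same allele.

    Raises
    ------
    KeyError
        If an affinity entry or the gene's expression value is missing
        (no silent defaults).
    """
    calls: list[NeoantigenCall] = []
    for pair in pairs:
        if pair.gene not in expression:
            raise KeyError(f"no expression value for gene {pair.gene!r}")
        expressed = float(expression[pair.gene]) > 0.0
        for allele in alleles:
            mut_ic50 = _ic50(affinity, pair.mut_peptide, allele)
            wt_ic50 = _ic50(affinity, pair.wt_peptide, allele)
            calls.append(
                NeoantigenCall(
                    pair=pair,
                    allele=allele,
                    mut_ic50=mut_ic50,
                    wt_ic50=wt_ic50,
                    expressed=expressed,
                    is_neoantigen=(mut_ic50 < mut_cut and wt_ic50 > wt_cut and expressed),
                )
            )
    return calls


def neoantigen_burden(calls: Iterable[NeoantigenCall], unit: str = "peptide") -> int:
    """Count neoantigens among calls.

    ``unit="peptide"`` counts distinct mutant peptides passing on at
    least one allele; ``"peptide_allele"`` counts passing
    (peptide, allele) pairs.
    """
    if unit not in {"peptide", "peptide_allele"}:
        raise ValueError(f"unknown burden unit {unit!r}")
    passing = [c for c in calls if c.is_neoantigen]
    if unit == "peptide_allele":
        return len({(c.pair.mut_peptide, c.allele) for c in passing})
    return len({c.pair.mut_peptide for c in passing})


class ToyPredictor:
    """Deterministic position-weight IC50 stand-in for an MHC predictor.

    Each allele gets a fixed 9 × 20 residue weight matrix derived from a
    seed constant and a hash of the allele name; a peptide's IC50 is a
    log-linear function of its summed weights, centred at 500 nM so that
    realistic peptide sets span both sides of the binding threshold.
    Identical inputs always give identical outputs.
    """

    def __init__(self, seed_constant: int = 17, scale: float = 0.8):
        self.seed_constant = int(seed_constant)
        self.scale = float(scale)
        self._matrices: dict[str, np.ndarray] = {}

    def _matrix(self, allele: str) -> np.ndarray:
        if allele not in self._matrices:
            seed = (self.seed_constant * 2654435761 + zlib.crc32(allele.encode())) % (2**31)
            rng = np.random.default_rng(seed)
            self._matrices[allele] = rng.normal(0.0, 1.0, size=(9, 20))
        return self._matrices[allele]

    def _encode(self, peptide: str) -> np.ndarray:
        if len(peptide) != 9:
            raise ValueError(f"toy predictor scores 9-mers only (got length {len(peptide)})")
        try:
            return np.array([_AA_INDEX[aa] for aa in peptide])
        except KeyError as exc:
            raise ValueError(f"non-standard residue in peptide {peptide!r}") from exc

    def __call__(self, peptide: str, allele: str) -> float:
        weights = self._matrix(allele)
        score = float(weights[np.arange(9), self._encode(peptide)].sum())
        return 500.0 * float(np.exp(self.scale * score))

    def score_many(self, peptides: Sequence[str], allele: str) -> np.ndarray:
        """Vectorized scoring of many 9-mers on one allele."""
        weights = self._matrix(allele)
        if not peptides:
            return np.zeros(0)
        codes = np.array([[_AA_INDEX[aa] for aa in p] for p in peptides])
        if codes.shape[1] != 9:
            raise ValueError("toy predictor scores 9-mers only")
        scores = weights[np.arange(9)[None, :], codes].sum(axis=1)
        return 500.0 * np.exp(self.scale * scores)
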