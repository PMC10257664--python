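"""Turn somatic coding variants into candidate mutant peptides.

A tumor-specific (neo)antigen candidate starts life as a somatic coding
change — a missense SNV, an in-frame indel, or a frameshift — in a
transcript's coding sequence (CDS).  This module edits the CDS, translates
both alleles, tiles short peptide windows (8–11-mers by default, the
MHC class I ligand range) across the changed residues, and applies the two
upstream filters of the selection pipeline:

* variants must have a variant allele frequency (VAF) strictly above a
  cutoff (0.01 by default), and
* mutant peptides that occur verbatim anywhere in the reference proteome
  are discarded (they are not tumor-specific).

It also provides the tumor mutation burden (TMB) helper, expressed as
nonsynonymous mutations per megabase of exome.

All coordinates are 1-based inclusive, on the CDS for variants and on the
mutant protein for peptide windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DEFAULT_LENGTHS = (8, 9, 10, 11)
_VALID_BASES = frozenset("ACGT")


class VariantKind(str, Enum):
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    FRAMESHIFT = "frameshift"


class InvalidSequenceError(ValueError):
    """A nucleotide or peptide string contains characters outside its alphabet."""


class ReferenceMismatchError(ValueError):
    """Variant ref_bases disagree with the supplied CDS at cds_pos."""


@dataclass(frozen=True)
class Variant:
    """One somatic coding change with its allele frequency and gene linkage."""

    id: str
    gene_id: str
    transcript_id: str
    kind: VariantKind
    cds_pos: int  # 1-based on the coding sequence
    ref_bases: str
    alt_bases: str
    vaf: float

    def __post_init__(self) -> None:
        if self.ref_bases == self.alt_bases:
            raise ValueError(f"{self.id}: ref equals alt")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"{self.id}: VAF {self.vaf} outside [0, 1]")
        if self.cds_pos < 1:
            raise ValueError(f"{self.id}: cds_pos must be >= 1")
        shifted = abs(len(self.ref_bases) - len(self.alt_bases)) % 3 != 0
        if shifted != (self.kind is VariantKind.FRAMESHIFT):
            raise ValueError(
                f"{self.id}: kind {self.kind.value} inconsistent with "
                f"ref/alt length difference"
            )


@dataclass(frozen=True)
class PeptidePair:
    """A mutant k-mer window and, when defined, its matched wild-type window.

    ``wt_peptide`` is ``None`` for windows containing residues with no
    wild-type counterpart (frameshift-derived residues, or residues around
    an in-frame insertion/deletion junction).
    """

    variant_id: str
    mut_peptide: str
    wt_peptide: str | None
    protein_start: int  # 1-based on the mutant protein
    length: int


class ProteomeIndex:
    """Exact k-mer membership over a reference proteome.

    Used to discard mutant peptides whose sequence already occurs in the
    normal proteome (self peptides are not neoantigens).
    """

    def __init__(self, proteins: Iterable[str], kmer_lengths: Iterable[int],
                 source: str = "user") -> None:
        self.source = source
        self.kmer_lengths = frozenset(int(k) for k in kmer_lengths)
        self._kmers: dict[int, set[str]] = {k: set() for k in self.kmer_lengths}
        for protein in proteins:
            for k in self.kmer_lengths:
                bucket = self._kmers[k]
                for i in range(len(protein) - k + 1):
                    bucket.add(protein[i:i + k])

    def __contains__(self, peptide: str) -> bool:
        k = len(peptide)
        if k not in self._kmers:
            raise KeyError(f"index not built for peptide length {k}")
        return peptide in self._kmers[k]


def translate_cds(cds: str) -> str:
    """Translate a coding sequence, stopping at the first stop codon.

    A trailing incomplete codon is ignored.  Raises
    :class:`InvalidSequenceError` on non-ACGT characters.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise InvalidSequenceError("CDS shorter than one codon")
    if not set(cds) <= _VALID_BASES:
        bad = sorted(set(cds) - _VALID_BASES)
        raise InvalidSequenceError(f"non-ACGT characters in CDS: {bad}")
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate(to_stop=True))


def apply_variant(cds: str, variant: Variant) -> str:
    """Translate the CDS after substituting ``alt_bases`` for ``ref_bases``.

    For frameshift variants the downstream residues reflect the shifted
    reading frame; translation truncates at the first stop either way.
    """
    start = variant.cds_pos - 1
    end = start + len(variant.ref_bases)
    if end > len(cds):
        raise ReferenceMismatchError(
            f"{variant.id}: variant extends past CDS end")
    observed = cds[start:end].upper()
    if observed != variant.ref_bases.upper():
        raise ReferenceMismatchError(
            f"{variant.id}: expected {variant.ref_bases!r} at CDS position "
            f"{variant.cds_pos}, found {observed!r}")
    edited = cds[:start] + variant.alt_bases + cds[end:]
    return translate_cds(edited)


def enumerate_windows(
    wt_protein: str,
    mut_protein: str,
    changed_positions: Iterable[int],
    lengths: Iterable[int] = DEFAULT_LENGTHS,
    *,
    variant_id: str = "",
    wt_aligned: bool = True,
) -> list[PeptidePair]:
    """Tile every k-mer of ``mut_protein`` covering a changed residue.

    ``changed_positions`` are 1-based on the mutant protein.  Windows are
    clipped at the protein ends.  When ``wt_aligned`` is true (substitution
    variants: the two proteins share coordinates) the same-coordinate window
    of ``wt_protein`` is attached as the wild-type partner; otherwise
    ``wt_peptide`` is ``None``.
    """
    changed = sorted({int(p) for p in changed_positions})
    if not changed:
        raise ValueError("changed_positions must be nonempty")
    pairs: list[PeptidePair] = []
    seen: set[tuple[str, int, int]] = set()
    L = len(mut_protein)
    for k in sorted(int(x) for x in lengths):
        p_min, p_max = changed[0], changed[-1]
        lo = max(1, p_min - k + 1)
        hi = min(p_max, L - k + 1)
        for start in range(lo, hi + 1):
            window = range(start, start + k)
            if not any(p in window for p in changed):
                continue
            mut_pep = mut_protein[start - 1:start - 1 + k]
            if "*" in mut_pep:
                continue
            key = (mut_pep, start, k)
            if key in seen:
                continue
            seen.add(key)
            wt_pep: str | None = None
            if wt_aligned:
                wt_pep = wt_protein[start - 1:start - 1 + k]
                if len(wt_pep) != k:
                    wt_pep = None
            pairs.append(PeptidePair(variant_id, mut_pep, wt_pep, start, k))
    if not pairs:
        logger.warning("no peptide windows for variant %r "
                       "(mutation beyond truncated protein end?)", variant_id)
    return pairs


def changed_protein_positions(wt_protein: str, mut_protein: str,
                              variant: Variant) -> set[int]:
    """1-based mutant-protein positions carrying variant-derived residues.

    Substitutions: the affected codon span, restricted to residues that
    actually differ (a synonymous edit yields the empty set).  In-frame
    indels: the block between the longest common prefix and suffix; a clean
    deletion marks the junction residue.  Frameshifts: everything from the
    first out-of-frame codon to the (truncated) end of the mutant protein.
    """
    first_codon = (variant.cds_pos - 1) // 3 + 1  # 1-based aa index
    if variant.kind is VariantKind.FRAMESHIFT:
        if first_codon > len(mut_protein):
            return set()
        start = first_codon
        # residues before the edited codon are unchanged; everything from the
        # first edited codon onward is novel-frame once sequences diverge
        while (start <= len(mut_protein) and start <= len(wt_protein)
               and mut_protein[start - 1] == wt_protein[start - 1]):
            start += 1
        return set(range(start, len(mut_protein) + 1))
    if len(variant.ref_bases) == len(variant.alt_bases):
        last_codon = (variant.cds_pos + len(variant.ref_bases) - 2) // 3 + 1
        return {
            p for p in range(first_codon, last_codon + 1)
            if p <= len(mut_protein) and (
                p > len(wt_protein) or mut_protein[p - 1] != wt_protein[p - 1])
        }
    # in-frame insertion or deletion: bracket the novel block
    lcp = 0
    while (lcp < len(wt_protein) and lcp < len(mut_protein)
           and wt_protein[lcp] == mut_protein[lcp]):
        lcp += 1
    lcs = 0
    while (lcs < len(wt_protein) - lcp and lcs < len(mut_protein) - lcp
           and wt_protein[-1 - lcs] == mut_protein[-1 - lcs]):
        lcs += 1
    block = set(range(lcp + 1, len(mut_protein) - lcs + 1))
    if not block and len(mut_protein) > 0:
        # pure deletion: mark the junction residue so windows spanning it
        # are still enumerated (the junction k-mers are novel)
        block = {min(lcp + 1, len(mut_protein))}
    return block


def peptides_for_variant(
    cds: str,
    variant: Variant,
    lengths: Iterable[int] = DEFAULT_LENGTHS,
) -> list[PeptidePair]:
    """CDS + variant -> tiled :class:`PeptidePair` list.

    Wild-type partner windows are attached only for length-preserving
    substitutions; indel- and frameshift-derived windows have no aligned
    wild-type counterpart.
    """
    wt_protein = translate_cds(cds)
    mut_protein = apply_variant(cds, variant)
    changed = changed_protein_positions(wt_protein, mut_protein, variant)
    if not changed:
        logger.warning("variant %s changes no residue (synonymous or beyond "
                       "truncation)", variant.id)
        return []
    wt_aligned = (variant.kind is VariantKind.MISSENSE
                  or (variant.kind is VariantKind.INFRAME_INDEL
                      and len(variant.ref_bases) == len(variant.alt_bases)))
    return enumerate_windows(wt_protein, mut_protein, changed, lengths,
                             variant_id=variant.id, wt_aligned=wt_aligned)


def filter_vaf(variants: Sequence[Variant], threshold: float = 0.01) -> list[Variant]:
    """Keep variants with VAF strictly greater than ``threshold``."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1)")
    return [v for v in variants if v.vaf > threshold]


def filter_reference_identity(pairs: Sequence[PeptidePair],
                              index: ProteomeIndex) -> list[PeptidePair]:
    """Drop pairs whose mutant peptide occurs verbatim in the reference proteome."""
    missing = {p.length for p in pairs} - index.kmer_lengths
    if missing:
        raise ValueError(f"proteome index lacks k-mer lengths {sorted(missing)}")
    return [p for p in pairs if p.mut_peptide not in index]


def tmb(n_nonsynonymous: int, exome_size_mb: float) -> float:
    """Tumor mutation burden: nonsynonymous mutations per megabase of exome."""
    if exome_size_mb <= 0:
        raise ValueError("exome size must be positive")
    return n_nonsynonymous / exome_size_mb


def read_variants_vcf(path) -> list[Variant]:
    """Read coding variants from a minimal VCF v4.x subset.

    Required INFO keys: GENE, TRANSCRIPT, CDSPOS (1-based position on the
    transcript CDS), VAF and KIND (missense / inframe_indel / frameshift).
    Record IDs become variant ids; REF/ALT are interpreted on the CDS
    strand.  A symbolic deletion keeps the shared anchor base out of the
    edit by trimming the common prefix of REF and ALT.
    """
    from cyvcf2 import VCF

    variants = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        ref, alt = rec.REF, rec.ALT[0] if rec.ALT else ""
        cds_pos = int(info["CDSPOS"])
        # trim the shared leading anchor base VCF uses for indels
        while ref and alt and ref[0] == alt[0]:
            ref, alt, cds_pos = ref[1:], alt[1:], cds_pos + 1
        variants.append(Variant(
            id=rec.ID or f"{rec.CHROM}:{rec.POS}",
            gene_id=str(info["GENE"]),
            transcript_id=str(info["TRANSCRIPT"]),
            kind=VariantKind(str(info["KIND"])),
            cds_pos=cds_pos,
            ref_bases=ref,
            alt_bases=alt,
            vaf=float(info["VAF"]),
        ))
    return variants


def write_pairs_tsv(pairs: Sequence[PeptidePair], path) -> None:
    """Peptide-pair TSV: variant_id, mut_peptide, wt_peptide, start, length."""
    import pandas as pd

    rows = [{"variant_id": p.variant_id, "mut_peptide": p.mut_peptide,
             "wt_peptide": p.wt_peptide if p.wt_peptide is not None else "",
             "protein_start": p.protein_start, "length": p.length}
            for p in pairs]
    pd.DataFrame(rows, columns=["variant_id", "mut_peptide", "wt_peptide",
                                "protein_start", "length"]).to_csv(
        path, sep="\t", index=False)
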