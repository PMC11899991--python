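"""Protein-guided back-translation into in-frame codon alignments.

The :class:`CodonAlignment` produced here is the substrate for pairwise
Ka/Ks estimation (:mod:`gramevol.kaks`) and codon site models
(:mod:`gramevol.sitemodels`). Back-translation follows the PAL2NAL logic:
each aligned protein column maps to the codon that encodes it, protein
gaps map to gap triplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from ._codons import stop_codons, translate_codon

GAP_CODON = "---"


class CodonAlignmentError(ValueError):
    """Raised when sequences cannot form a valid in-frame codon alignment."""


@dataclass
class CodonAlignment:
    """An aligned set of in-frame codon sequences.

    Each row is a list of 3-character cells: either a codon over ACGT or the
    gap triplet ``---``. ``column_index`` maps current columns back to the
    columns of the alignment this one was derived from (identity for a fresh
    alignment).
    """

    taxa: list[str]
    codons: list[list[str]]
    genetic_code: int = 1
    column_index: list[int] = field(default_factory=list)
    site_classes: list[int] | None = None  # simulation ground truth, if any

    def __post_init__(self):
        if len(self.taxa) != len(self.codons):
            raise CodonAlignmentError("one codon row required per taxon")
        lengths = {len(row) for row in self.codons}
        if len(lengths) > 1:
            raise CodonAlignmentError("ragged codon alignment")
        for taxon, row in zip(self.taxa, self.codons):
            for c, cell in enumerate(row):
                if len(cell) != 3:
                    raise CodonAlignmentError(f"{taxon}: cell {c} is not a triplet")
                if cell != GAP_CODON and cell in stop_codons(self.genetic_code):
                    raise CodonAlignmentError(f"{taxon}: internal stop codon at column {c}")
        if not self.column_index:
            self.column_index = list(range(self.n_codons))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.codons[0]) if self.codons else 0

    def row(self, taxon: str) -> list[str]:
        return self.codons[self.taxa.index(taxon)]

    def sequence(self, taxon: str) -> str:
        return "".join(self.row(taxon))

    def column(self, c: int) -> list[str]:
        return [row[c] for row in self.codons]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon, row in zip(self.taxa, self.codons):
                fh.write(f">{taxon}\n{''.join(row)}\n")

    def to_phylip(self, path) -> None:
        """PHYLIP-sequential with full (relaxed) names."""
        with open(path, "w") as fh:
            fh.write(f" {self.n_taxa} {self.n_codons * 3}\n")
            for taxon, row in zip(self.taxa, self.codons):
                fh.write(f"{taxon}  {''.join(row)}\n")


def _normalize_nt(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _strip_terminal_stop(cds: str, code_id: int) -> str:
    if len(cds) >= 3 and cds[-3:] in stop_codons(code_id):
        return cds[:-3]
    return cds


def backtranslate(
    protein_alignment: Sequence[tuple[str, str]] | dict[str, str],
    cds_by_taxon: dict[str, str],
    genetic_code: int = 1,
) -> CodonAlignment:
    """Convert a protein alignment plus per-taxon CDS into a codon alignment.

    Parameters
    ----------
    protein_alignment:
        ``(taxon, aligned protein)`` pairs or a mapping; rows must share one
        length. Gaps are ``-``.
    cds_by_taxon:
        Unaligned coding sequences; each must translate (after terminal-stop
        stripping) to its taxon's ungapped protein row.

    Raises
    ------
    CodonAlignmentError
        On CDS/protein discordance (with the first discordant residue), CDS
        length not divisible by 3, or an internal stop codon.
    """
    items = list(protein_alignment.items()) if isinstance(protein_alignment, dict) else list(protein_alignment)
    if not items:
        raise CodonAlignmentError("empty protein alignment")
    aln_len = len(items[0][1])
    taxa, rows = [], []
    for taxon, prot in items:
        prot = prot.upper()
        if len(prot) != aln_len:
            raise CodonAlignmentError(f"{taxon}: ragged protein alignment")
        if taxon not in cds_by_taxon:
            raise CodonAlignmentError(f"{taxon}: no CDS provided")
        cds = _strip_terminal_stop(_normalize_nt(cds_by_taxon[taxon]), genetic_code)
        if len(cds) % 3:
            raise CodonAlignmentError(f"{taxon}: CDS length {len(cds)} not a multiple of 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        for i, codon in enumerate(codons):
            if codon in stop_codons(genetic_code):
                raise CodonAlignmentError(f"{taxon}: internal stop codon at CDS codon {i + 1}")
        ungapped = prot.replace("-", "")
        if len(codons) != len(ungapped):
            raise CodonAlignmentError(
                f"{taxon}: CDS encodes {len(codons)} residues but protein row has {len(ungapped)}"
            )
        for i, (codon, aa) in enumerate(zip(codons, ungapped)):
            if translate_codon(codon, genetic_code) != aa:
                raise CodonAlignmentError(
                    f"{taxon}: CDS/protein mismatch at residue {i + 1} "
                    f"({codon} encodes {translate_codon(codon, genetic_code)}, protein has {aa})"
                )
        it = iter(codons)
        rows.append([GAP_CODON if aa == "-" else next(it) for aa in prot])
        taxa.append(taxon)
    return CodonAlignment(taxa=taxa, codons=rows, genetic_code=genetic_code)


def filter_columns(
    aln: CodonAlignment, policy: Literal["any_gap", "ambiguity", "none"] = "any_gap"
) -> CodonAlignment:
    """Drop codon columns per ``policy``; original indices kept as metadata.

    ``any_gap`` removes columns containing any gap cell; ``ambiguity``
    additionally removes columns with any non-ACGT character; ``none`` is the
    identity. Idempotent for a fixed policy.
    """
    if policy == "none":
        keep = list(range(aln.n_codons))
    elif policy in ("any_gap", "ambiguity"):
        keep = []
        for c in range(aln.n_codons):
            col = aln.column(c)
            if any(cell == GAP_CODON for cell in col):
                continue
            if policy == "ambiguity" and any(set(cell) - set("ACGT") for cell in col):
                continue
            keep.append(c)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    if not keep:
        raise CodonAlignmentError("filtering removed every column")
    return CodonAlignment(
        taxa=list(aln.taxa),
        codons=[[row[c] for c in keep] for row in aln.codons],
        genetic_code=aln.genetic_code,
        column_index=[aln.column_index[c] for c in keep],
        site_classes=[aln.site_classes[c] for c in keep] if aln.site_classes else None,
    )


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def translate_cds(cds: str, genetic_code: int = 1) -> str:
    cds = _strip_terminal_stop(_normalize_nt(cds), genetic_code)
    return str(Seq(cds).translate(table=genetic_code))
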