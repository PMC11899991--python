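"""Promoter extraction and cis-acting element scanning.

Fixed-length upstream regions (default 2000 bp, anchored at the
translation start) are scanned on both strands against a catalog of
degenerate IUPAC consensus patterns for plant cis-acting elements
(PlantCARE-style names: ARE, ABRE, MBS, G-box, CGTCA-motif, ...).
Matching is exact degenerate matching — no mismatches, no PWM scoring;
overlapping hits are all reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifDef:
    name: str
    iupac: str
    category: str  # phytohormone | light | stress | development

    def __post_init__(self):
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC letters {sorted(bad)}")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def load_catalog(path=None) -> list[MotifDef]:
    """Load the bundled cis-element catalog (or a user YAML of the same shape)."""
    if path is None:
        text = resources.files("gramevol.data").joinpath("cis_elements.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    motifs = [MotifDef(name=m["name"], iupac=m["iupac"].upper(), category=m["category"]) for m in raw["motifs"]]
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate motif names in catalog")
    return motifs


def extract_upstream(
    genome: dict[str, str],
    annotation: pd.DataFrame,
    length: int = 2000,
) -> dict[str, tuple[str, bool]]:
    """Upstream promoter sequence per gene, reverse-complemented on '-'.

    Coordinates are 1-based inclusive; the promoter is the ``length`` bases
    immediately 5' of the translation start (gene start for '+', gene end
    for '-'). Returns gene -> (sequence, truncated_flag); truncation happens
    at chromosome edges.
    """
    out = {}
    for r in annotation.itertuples():
        if r.chromosome not in genome:
            raise KeyError(f"unknown chromosome {r.chromosome!r}")
        chrom = genome[r.chromosome].upper()
        if r.strand == "+":
            lo = max(0, r.start - 1 - length)
            seq = chrom[lo : r.start - 1]
            truncated = r.start - 1 < length
        else:
            seq = reverse_complement(chrom[r.end : r.end + length])
            truncated = len(chrom) - r.end < length
        out[r.gene_id] = (seq, truncated)
    return out


def _pattern_regex(iupac: str) -> re.Pattern:
    return re.compile("(?=(" + "".join(IUPAC[c] for c in iupac.upper()) + "))")


def scan(promoters: dict[str, str], catalog: list[MotifDef]) -> pd.DataFrame:
    """All degenerate matches of every catalog motif on both strands.

    Positions are 1-based on the promoter as given (5'->3' toward the ATG);
    minus-strand hits are reported at the position of the match on the given
    sequence. Output is sorted by (gene, start, motif, strand).
    """
    rows = []
    for gene, seq in sorted(promoters.items()):
        seq = seq.upper()
        for motif in catalog:
            fwd = _pattern_regex(motif.iupac)
            rcp = _pattern_regex(reverse_complement(motif.iupac))
            for m in fwd.finditer(seq):
                rows.append({"gene": gene, "motif": motif.name, "start": m.start() + 1, "strand": "+"})
            for m in rcp.finditer(seq):
                rows.append({"gene": gene, "motif": motif.name, "start": m.start() + 1, "strand": "-"})
    out = pd.DataFrame(rows, columns=["gene", "motif", "start", "strand"])
    return out.sort_values(["gene", "start", "motif", "strand"], kind="stable").reset_index(drop=True)


def count_matrix(hits: pd.DataFrame, genes: list[str], catalog: list[MotifDef]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes x motifs hit counts plus per-category rollups (zero-filled)."""
    motifs = [m.name for m in catalog]
    mat = pd.DataFrame(0, index=genes, columns=motifs)
    if len(hits):
        counted = hits.groupby(["gene", "motif"]).size()
        for (gene, motif), n in counted.items():
            if gene in mat.index and motif in mat.columns:
                mat.loc[gene, motif] = n
    category_of = {m.name: m.category for m in catalog}
    categories = sorted({m.category for m in catalog})
    roll = pd.DataFrame(0, index=genes, columns=categories)
    for motif in motifs:
        roll[category_of[motif]] += mat[motif]
    return mat, roll
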