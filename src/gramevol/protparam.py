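"""Protein physicochemical properties and pairwise identity.

Length, average molecular weight, theoretical pI (Bjellqvist pKa set),
Guruprasad instability index and Kyte–Doolittle GRAVY follow the ExPASy
ProtParam conventions via Biopython; Ikai's aliphatic index is computed
here (AI = X(Ala) + 2.9·X(Val) + 3.9·(X(Ile) + X(Leu)) on mole percents).
Percent identity uses columns with a non-gap residue in at least one of
the two rows as the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS = set("BZX")

#: instability-index threshold below which a protein is conventionally "stable"
STABLE_INSTABILITY_THRESHOLD = 40.0


@dataclass
class ProtProperties:
    length: int
    mw: float
    pi: float
    instability_index: float
    aliphatic_index: float
    gravy: float
    stable: bool  # instability index < 40


def _normalize(sequence: str, policy: Literal["strict", "lenient"]) -> str:
    seq = sequence.upper().strip("*")
    if not seq:
        raise ValueError("empty sequence")
    unknown = set(seq) - CANONICAL - AMBIGUOUS
    if unknown:
        raise ValueError(f"unknown residues: {sorted(unknown)}")
    if set(seq) & AMBIGUOUS:
        if policy == "strict":
            raise ValueError("ambiguous residues (B/Z/X) under strict policy")
        seq = "".join(r for r in seq if r in CANONICAL)
        if not seq:
            raise ValueError("no canonical residues left after removing ambiguity")
    return seq


def aliphatic_index(sequence: str) -> float:
    """Ikai's aliphatic index on mole-percent composition."""
    n = len(sequence)
    x = {aa: 100.0 * sequence.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def compute_properties(sequence: str, policy: Literal["strict", "lenient"] = "strict") -> ProtProperties:
    """ExPASy-style physicochemical descriptors for one protein.

    Under the ``lenient`` policy, B/Z/X residues are dropped before the
    composition-based descriptors are computed (charge-neutral for pI).
    """
    seq = _normalize(sequence, policy)
    analysis = ProteinAnalysis(seq)
    return ProtProperties(
        length=len(seq),
        mw=analysis.molecular_weight(),
        pi=analysis.isoelectric_point(),
        instability_index=analysis.instability_index() if len(seq) > 1 else 0.0,
        aliphatic_index=aliphatic_index(seq),
        gravy=analysis.gravy(),
        stable=(analysis.instability_index() if len(seq) > 1 else 0.0) < STABLE_INSTABILITY_THRESHOLD,
    )


def properties_table(records: Iterable[tuple[str, str]], policy: Literal["strict", "lenient"] = "strict") -> pd.DataFrame:
    rows = []
    for name, seq in records:
        p = compute_properties(seq, policy)
        rows.append(
            {
                "id": name, "length": p.length, "mw": p.mw, "pi": p.pi,
                "instability_index": p.instability_index,
                "aliphatic_index": p.aliphatic_index, "gravy": p.gravy,
                "stable": p.stable,
            }
        )
    return pd.DataFrame(rows)


def identity_matrix(aligned: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Symmetric percent-identity matrix for an aligned protein set.

    Scored columns for a pair are those where at least one of the two rows
    is non-gap; identities require both residues present and equal. A pair
    with no overlapping non-gap columns scores 0 with a warning.
    """
    names = [n for n, _ in aligned]
    seqs = [s.upper() for _, s in aligned]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("ragged alignment")
    arr = np.array([list(s) for s in seqs])
    gap = arr == "-"
    n = len(names)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            scored = ~(gap[i] & gap[j])
            both = ~gap[i] & ~gap[j]
            if not both.any():
                warnings.warn(f"{names[i]}/{names[j]}: no overlapping residues; identity set to 0", stacklevel=2)
                ident = 0.0
            else:
                matches = (arr[i] == arr[j]) & both
                ident = 100.0 * matches.sum() / scored.sum()
            out[i, j] = out[j, i] = ident
    return pd.DataFrame(out, index=names, columns=names)


def summarize_family(properties: pd.DataFrame, exon_counts: Sequence[int] | None = None) -> dict:
    """Family-level summary: length extremes with gene ids, pI and MW ranges,
    mean pI, count of stable proteins, and the modal exon count."""
    if properties.empty:
        raise ValueError("empty property table")
    p = properties
    summary = {
        "n": len(p),
        "min_length": int(p["length"].min()),
        "min_length_id": p.loc[p["length"].idxmin(), "id"],
        "max_length": int(p["length"].max()),
        "max_length_id": p.loc[p["length"].idxmax(), "id"],
        "pi_min": float(p["pi"].min()),
        "pi_max": float(p["pi"].max()),
        "pi_mean": float(p["pi"].mean()),
        "mw_min": float(p["mw"].min()),
        "mw_max": float(p["mw"].max()),
        "n_stable": int((p["instability_index"] < STABLE_INSTABILITY_THRESHOLD).sum()),
    }
    if exon_counts is not None and len(exon_counts):
        counts = pd.Series(list(exon_counts))
        mode = counts.mode().iloc[0]
        summary["modal_exons"] = int(mode)
        summary["modal_exons_fraction"] = float((counts == mode).mean())
        summary["exon_min"] = int(counts.min())
        summary["exon_max"] = int(counts.max())
    return summary
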