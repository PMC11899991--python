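"""Bundled reference tables for the Poaceae type-B response regulator family.

Small published summary tables for the 60-gene family across six grass
species (rice, *Panicum hallii*, sorghum, foxtail millet, maize, wheat):
per-protein physicochemical properties, pairwise Ka/Ks between rice genes
and their homologs, per-cluster site-model statistics, and the curated
tandem/segmental duplication pair lists. These anchor the bookkeeping
operations (ratio and divergence-time recomputation, duplication counting,
family summaries) without any genome downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: haplotype group sizes of the rice diversity panel (Hap1..Hap5)
HAPLOTYPE_GROUP_SIZES = (189, 43, 6, 4, 3)
#: variant-site composition of the focal gene region
N_INDELS = 4
N_SNPS = 46
#: family size per species (rice, Panicum, sorghum, Setaria, maize, wheat)
GENES_PER_SPECIES = {
    "Oryza sativa": 6,
    "Panicum hallii": 7,
    "Sorghum bicolor": 11,
    "Setaria italica": 9,
    "Zea mays": 9,
    "Triticum aestivum": 18,
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("gramevol.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def protein_properties() -> pd.DataFrame:
    """Per-protein length, MW, pI, instability, aliphatic index and GRAVY."""
    return _read("rrb_protein_properties.tsv")


def pairwise_kaks() -> pd.DataFrame:
    """Published Ka, Ks, Ka/Ks and divergence time (MYA) for 55 rice-vs-other
    homolog pairs. ``ratio`` and ``mya`` are kept as printed (variable decimal
    places); ``ratio_decimals``/``mya_decimals`` record the printed precision."""
    df = _read("rrb_pairwise_kaks.tsv")
    raw = pd.read_csv(
        resources.files("gramevol.data").joinpath("rrb_pairwise_kaks.tsv").open(),
        sep="\t", dtype=str,
    )
    for col in ("ka", "ks", "ratio", "mya"):
        df[f"{col}_decimals"] = raw[col].map(lambda s: len(s.split(".")[1]) if "." in s else 0)
    return df


def ogc_selection() -> pd.DataFrame:
    """Per-cluster site-model statistics: single-ratio omega, the three LRT
    2*dlnL statistics, and the beta-and-omega model parameter estimates."""
    return _read("rrb_ogc_selection.tsv")


def duplication_pairs() -> pd.DataFrame:
    """Curated duplication gene pairs: species, type (segmental pair or
    tandem event), and slash-joined member genes (3-gene tandem arrays are
    single events)."""
    return _read("rrb_duplication_pairs.tsv")
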