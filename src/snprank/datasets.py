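"""Packaged example tables: the published per-variant annotation tables
transcribed as TSV fixtures, plus a small synthetic ortholog alignment.

The tables are stored exactly as printed in their source, including its
internal inconsistencies (e.g. residue identities that disagree with the
surrounding text); loaders do not reconcile them.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from Bio.Align import MultipleSeqAlignment

from .model import AnnotatedVariant, PTMSite
from .ptm import SiteRegistry, read_alignment
from .regulatory import RegulatoryRow, read_regulatory_table
from .tables import read_ptm_table, read_variant_table


def _data_path(name: str) -> Path:
    return Path(resources.files("snprank").joinpath("data", name))


def regulatory_sites_path() -> Path:
    return _data_path("regulatory_sites.tsv")


def conserved_variants_path() -> Path:
    return _data_path("conserved_variants.tsv")


def ptm_sites_path() -> Path:
    return _data_path("ptm_sites.tsv")


def ortholog_alignment_path() -> Path:
    return _data_path("synthetic_ortholog_alignment.fasta")


def load_regulatory_sites() -> list[RegulatoryRow]:
    """Regulatory-region SNPs with splicing-element, UTR-motif and FastSNP
    annotations; ``bold`` marks rows the source highlighted as significant
    by both annotation tools."""
    return read_regulatory_table(regulatory_sites_path())


def load_conserved_variants() -> list[AnnotatedVariant]:
    """nsSNPs with ConSurf conservation grades and burial status."""
    return read_variant_table(conserved_variants_path())


def load_ptm_sites() -> list[PTMSite]:
    """Predicted PTM sites per tool; ``experimental`` marks positions with
    published experimental support."""
    return read_ptm_table(ptm_sites_path())


def load_ptm_registry() -> SiteRegistry:
    return SiteRegistry.from_sites(load_ptm_sites())


def load_ortholog_alignment() -> MultipleSeqAlignment:
    """A small SYNTHETIC ortholog alignment (generated, not biological data)
    shaped like a human-vs-vertebrates protein alignment: reference id
    ``human``, identical columns at a few sites and one deletion gap."""
    return read_alignment(ortholog_alignment_path(), fmt="fasta")
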