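"""Packaged reference fixtures: the nine trifoliate-orange miRNAs, their
Arabidopsis orthologs and precursor regions, the 27 published RACE/qPCR
primers with their GSP1 core offsets, the published 5'-RACE terminus
frequency strings, and the RLM-5'RACE target-gene primers.

The frequency strings and RLM-RACE primers are experimental outcomes and
ship as data only; everything else is both data and regression surface for
the primer-design rules.
"""

from __future__ import annotations

import csv
from importlib import resources

import yaml

from ..seqcore import NucSequence, read_fasta


def _path(name: str):
    return resources.files(__package__) / name


def table1_mirnas() -> list[NucSequence]:
    """The nine validated mature ptr-miRNAs (RNA)."""
    return read_fasta(str(_path("table1_mirnas.fa")), "RNA")


def table1_ath_orthologs() -> list[NucSequence]:
    """Arabidopsis/other-plant ortholog matures, same ids as the PT set."""
    return read_fasta(str(_path("table1_ath_orthologs.fa")), "RNA")


def table1_precursor_regions() -> list[NucSequence]:
    """Precursor regions spanning each mature with a few flanking bases."""
    return read_fasta(str(_path("table1_precursor_regions.fa")), "RNA")


def table2_primers() -> dict[str, dict[str, str]]:
    """Published GSP1/GSP2/GSP3 strings keyed by miRNA id."""
    with _path("table2_primers.tsv").open() as fh:
        return {
            row["mirna_id"]: {k: row[k] for k in ("gsp1", "gsp2", "gsp3")}
            for row in csv.DictReader(fh, delimiter="\t")
        }


def table1_frequencies() -> dict[str, dict[str, str]]:
    """Published 5'-RACE terminus frequency strings (PT and Arabidopsis)."""
    with _path("table1_frequencies.tsv").open() as fh:
        return {
            row["mirna_id"]: {
                "pt": row["race5_pt"], "ath": row["race5_ath"]
            }
            for row in csv.DictReader(fh, delimiter="\t")
        }


def table4_targets() -> list[dict[str, str]]:
    """RLM-5'RACE target genes and their (nested) gene-specific primers."""
    with _path("table4_targets.tsv").open() as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def gsp1_offsets() -> dict[str, int]:
    """Per-miRNA delta used by the published GSP1 primers."""
    with _path("gsp1_offsets.yaml").open() as fh:
        return {k: int(v) for k, v in yaml.safe_load(fh).items()}
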