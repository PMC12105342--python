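"""Horizontal-gene-transfer candidate screen from BLAST bitscores.

For each protein, the best (maximum) bitscore against each taxon-group
database is collected; the *h-index* of a non-metazoan group is that
group's best bitscore minus the best bitscore against non-Acari
invertebrates. A gene passes as an HGT candidate when its maximum h-index
exceeds 30 and the donor-group bitscore exceeds 100 (both strict). A group
without any hit contributes bitscore 0, so a gene hit only by a strong
non-metazoan donor still passes — the intended behaviour for genes of
non-metazoan origin. The taxon assignment of each database is trusted as
given; Acari exclusion is a property of database construction.
"""

from __future__ import annotations

import pandas as pd

from .io import parse_blast_tab  # noqa: F401  (re-exported parser)
from .simulate import NON_METAZOAN_GROUPS, TAXON_GROUPS

INVERTEBRATE_GROUP = "invertebrate_non_acari"


def best_scores(tables: dict[str, pd.DataFrame],
                protein_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-gene maximum bitscore per taxon group (0 when no hit).

    ``tables`` maps taxon-group label -> hit table (columns qseqid,
    bitscore at minimum). Pass ``protein_ids`` to include queries with no
    hit anywhere. Group labels must be unique and known.
    """
    for grp in tables:
        if grp not in TAXON_GROUPS:
            raise ValueError(f"unknown taxon group {grp!r}")
    index = pd.Index(protein_ids, name="gene_id") if protein_ids is not None \
        else pd.Index(sorted({q for df in tables.values()
                              for q in df["qseqid"]}), name="gene_id")
    out = pd.DataFrame(0.0, index=index, columns=list(TAXON_GROUPS))
    for grp, df in tables.items():
        if df.empty:
            continue
        best = df.groupby("qseqid")["bitscore"].max()
        best = best[best.index.isin(index)]
        out.loc[best.index, grp] = best.to_numpy(dtype=float)
    return out


def call_hgt(best: pd.DataFrame, h_min: float = 30.0,
             donor_min: float = 100.0) -> pd.DataFrame:
    """HGT candidate calls from per-group best bitscores.

    h_index(group) = best(group) - best(invertebrate_non_acari) for each
    non-metazoan group. The donor is the group with the highest h-index
    (ties: higher bitscore, then fixed group order); a gene passes iff its
    donor h-index > h_min and the donor bitscore > donor_min, strictly.
    """
    if h_min <= 0 or donor_min <= 0:
        raise ValueError("thresholds must be positive")
    inv = best[INVERTEBRATE_GROUP]
    rows = []
    for gid in best.index:
        h = {grp: float(best.at[gid, grp]) - float(inv[gid])
             for grp in NON_METAZOAN_GROUPS}
        donor = max(NON_METAZOAN_GROUPS,
                    key=lambda g: (h[g], float(best.at[gid, g]),
                                   -NON_METAZOAN_GROUPS.index(g)))
        donor_bits = float(best.at[gid, donor])
        row = {"gene_id": gid,
               **{f"best_{grp}": float(best.at[gid, grp]) for grp in TAXON_GROUPS},
               **{f"h_{grp}": h[grp] for grp in NON_METAZOAN_GROUPS},
               "donor_group": donor, "donor_bitscore": donor_bits,
               "h_index": h[donor],
               "passes": h[donor] > h_min and donor_bits > donor_min}
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def hgt_screen(tables: dict[str, pd.DataFrame],
               protein_ids: list[str] | None = None,
               h_min: float = 30.0, donor_min: float = 100.0) -> pd.DataFrame:
    """Convenience wrapper: best_scores + call_hgt."""
    return call_hgt(best_scores(tables, protein_ids), h_min=h_min,
                    donor_min=donor_min)
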