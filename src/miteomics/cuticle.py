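"""Cuticular-protein (CP) screens.

Two complementary strategies:

1. **Known families** — classification from domain annotations: the insect
   cuticle protein domain IPR000618 marks the CPR family (Rebers-Riddiford
   consensus); chitin-binding peritrophin-A domains (CBD: PF01607 /
   IPR036508 / IPR002557) mark CPAP proteins (analogous to peritrophins),
   excluding chitinases and chitin deacetylases; a low-complexity
   proline-rich sequence dense in PV/PY pairs marks CPLCP.

2. **CPH candidates** — novel "cuticular protein hypothetical" genes found
   by a filter cascade: (1) no functional annotation (no InterPro/Panther
   domain, GO, KO or in-house category), (2) expression within the top
   decile of whole-transcriptome mean TPM, (3) a signal peptide with
   predicted extracellular localization, and (4) at least one sequence
   trait typical of CPs — three or more AAP(A/V/L) motifs, glycine-dense
   regions, abundant PV/PY pairs, tandem repeats, hydrophobic-residue
   richness, or a cysteine-free mature peptide.

Trait thresholds are exposed in :class:`TraitParams`; the quantitative
defaults operationalize verbal criteria and are deliberately conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CBD_ACCESSIONS = frozenset({"PF01607", "IPR036508", "IPR002557"})
CPR_ACCESSION = "IPR000618"

#: domain accessions / in-house flags marking chitin-modifying enzymes that
#: carry CBDs but are not structural cuticle proteins
CHITINASE_DOMAINS = frozenset({"IPR001223", "IPR011583", "IPR002509"})
CHITINASE_FLAGS = frozenset({"chitinase", "chitin_deacetylase"})

NONPOLAR_RESIDUES = frozenset("GAVLIPFMW")

CP_FAMILIES = ("CPR", "CPAP", "CPLCP", "CPH", "none")


@dataclass(frozen=True)
class TraitParams:
    """Thresholds for the CP sequence-trait rules (per-residue units)."""

    min_aap_motifs: int = 3          # AAP(A|V|L) occurrences
    nonpolar_min_fraction: float = 0.5
    gly_window: int = 20             # residues
    gly_min_fraction: float = 0.5    # G fraction within the window
    pvpy_min_density: float = 0.03   # (PV+PY pairs) / length
    repeat_min_k: int = 2
    repeat_max_k: int = 10
    repeat_min_copies: int = 3
    repeat_min_coverage: float = 0.2  # fraction of sequence length


@dataclass
class ProteinRecord:
    """One protein with its annotation evidence.

    ``sp_cleavage_pos`` is the 1-based position of the last signal-peptide
    residue (0 when there is none); the mature peptide starts after it.
    """

    gene_id: str
    sequence: str
    domain_accessions: tuple[str, ...] = ()
    has_go: bool = False
    has_ko: bool = False
    inhouse_flags: frozenset[str] = frozenset()
    signal_peptide: bool = False
    sp_cleavage_pos: int = 0
    extracellular: bool = False
    mean_tpm: float = 0.0

    def __post_init__(self) -> None:
        if self.sp_cleavage_pos and self.sp_cleavage_pos >= len(self.sequence):
            raise ValueError("sp_cleavage_pos must be < sequence length")

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.sp_cleavage_pos:] if self.signal_peptide \
            else self.sequence


@dataclass
class CPCall:
    gene_id: str
    family: str
    cbd_count: int = 0
    traits: dict[str, float] = field(default_factory=dict)
    dropout_stage: str | None = None  # CPH screen: first failed filter


def records_from_tables(sequences: dict[str, str], annotations: pd.DataFrame,
                        mean_tpm: pd.Series | None = None) -> list[ProteinRecord]:
    """Assemble ProteinRecords from the FASTA + annotation (+ TPM) tables."""
    records = []
    for gid, seq in sequences.items():
        row = annotations.loc[gid]
        domains = tuple(d for d in str(row["domain_accessions"]).split(";") if d)
        flags = frozenset(f for f in str(row["inhouse_flags"]).split(";") if f)
        records.append(ProteinRecord(
            gene_id=gid, sequence=seq, domain_accessions=domains,
            has_go=bool(row["go_flag"]), has_ko=bool(row["ko_flag"]),
            inhouse_flags=flags, signal_peptide=bool(row["signal_peptide"]),
            sp_cleavage_pos=int(row["sp_cleavage_pos"]),
            extracellular=bool(row["extracellular"]),
            mean_tpm=float(mean_tpm.get(gid, 0.0)) if mean_tpm is not None else 0.0))
    return records


def aap_motif_count(sequence: str) -> int:
    """Occurrences of the AAP(A|V|L) tetrapeptide (overlaps allowed)."""
    n = 0
    for i in range(len(sequence) - 3):
        if sequence[i:i + 3] == "AAP" and sequence[i + 3] in "AVL":
            n += 1
    return n


def mature_is_cysteine_free(record: ProteinRecord) -> bool:
    """True iff the mature peptide (after SP cleavage) contains no cysteine."""
    return "C" not in record.mature_sequence


def _nonpolar_fraction(sequence: str) -> float:
    if not sequence:
        return 0.0
    return sum(1 for a in sequence if a in NONPOLAR_RESIDUES) / len(sequence)


def _max_gly_window_fraction(sequence: str, window: int) -> float:
    if not sequence:
        return 0.0
    if len(sequence) <= window:
        return sequence.count("G") / len(sequence)
    is_g = np.frombuffer(sequence.encode(), dtype=np.uint8) == ord("G")
    csum = np.concatenate([[0], np.cumsum(is_g)])
    return float((csum[window:] - csum[:-window]).max()) / window


def _pvpy_density(sequence: str) -> float:
    if not sequence:
        return 0.0
    pairs = sum(1 for i in range(len(sequence) - 1)
                if sequence[i] == "P" and sequence[i + 1] in "VY")
    return pairs / len(sequence)


def _best_tandem_repeat(sequence: str, params: TraitParams) -> tuple[bool, float]:
    """Scan k-mers (k in [repeat_min_k, repeat_max_k]) for tandem runs.

    Returns (qualifies, coverage): whether any unit repeats
    >= repeat_min_copies consecutive times while covering
    >= repeat_min_coverage of the sequence, and the largest coverage among
    qualifying runs (0 if none).
    """
    qualifies, best_cov = False, 0.0
    n = len(sequence)
    for k in range(params.repeat_min_k, params.repeat_max_k + 1):
        i = 0
        while i + k <= n:
            unit = sequence[i:i + k]
            copies = 1
            j = i + k
            while sequence[j:j + k] == unit:
                copies += 1
                j += k
            cov = copies * k / n
            if copies >= params.repeat_min_copies and \
                    cov >= params.repeat_min_coverage:
                qualifies = True
                best_cov = max(best_cov, cov)
            i += 1 if copies == 1 else (copies - 1) * k
    return qualifies, best_cov


def trait_scores(record: ProteinRecord,
                 params: TraitParams = TraitParams()) -> dict[str, float]:
    """Score the CP sequence traits; returns only the traits present.

    Values are the measured statistics (motif count, fractions, densities,
    repeat coverage). Sequences shorter than the glycine window are scored
    on the whole sequence.
    """
    seq = record.sequence
    mature = record.mature_sequence
    traits: dict[str, float] = {}
    aap = aap_motif_count(seq)
    if aap >= params.min_aap_motifs:
        traits["aap_motifs"] = float(aap)
    npf = _nonpolar_fraction(seq)
    if npf > params.nonpolar_min_fraction:
        traits["hydrophobic_rich"] = npf
    if mature and "C" not in mature:
        traits["cys_free"] = 1.0
    gw = _max_gly_window_fraction(seq, params.gly_window)
    if gw >= params.gly_min_fraction:
        traits["gly_dense"] = gw
    dens = _pvpy_density(seq)
    if dens >= params.pvpy_min_density:
        traits["pvpy_rich"] = dens
    has_repeat, cov = _best_tandem_repeat(seq, params)
    if has_repeat:
        traits["tandem_repeat"] = cov
    return traits


def _is_chitin_enzyme(record: ProteinRecord) -> bool:
    return bool(set(record.domain_accessions) & CHITINASE_DOMAINS) or \
        bool(record.inhouse_flags & CHITINASE_FLAGS)


def classify_known_cp(record: ProteinRecord,
                      params: TraitParams = TraitParams(),
                      min_proline_fraction: float = 0.15) -> CPCall:
    """Classify into the known CP families (CPR > CPAP > CPLCP > none).

    CPR requires IPR000618. CPAP requires >= 1 CBD accession instance and
    no chitinase/chitin-deacetylase evidence; ``cbd_count`` counts CBD
    accession instances in the annotation. CPLCP is an operational rule:
    PV/PY-pair density at the trait threshold plus a proline fraction of at
    least ``min_proline_fraction`` (heuristic — the family is defined by
    low-complexity proline richness).
    """
    cbd = sum(1 for d in record.domain_accessions if d in CBD_ACCESSIONS)
    if CPR_ACCESSION in record.domain_accessions:
        return CPCall(record.gene_id, "CPR", cbd_count=cbd)
    if cbd >= 1 and not _is_chitin_enzyme(record):
        return CPCall(record.gene_id, "CPAP", cbd_count=cbd)
    seq = record.sequence
    pro = seq.count("P") / len(seq) if seq else 0.0
    if _pvpy_density(seq) >= params.pvpy_min_density and \
            pro >= min_proline_fraction:
        return CPCall(record.gene_id, "CPLCP",
                      traits={"pvpy_rich": _pvpy_density(seq)})
    return CPCall(record.gene_id, "none", cbd_count=cbd)


def is_unannotated(record: ProteinRecord) -> bool:
    """No InterPro/Panther domain, GO, KO, or in-house category."""
    has_domain = any(d.startswith(("IPR", "PTHR"))
                     for d in record.domain_accessions)
    return not (has_domain or record.has_go or record.has_ko
                or record.inhouse_flags)


def expression_cutoff(mean_tpm: pd.Series, decile: float = 0.10) -> float:
    """Whole-transcriptome TPM cutoff for the top expression decile."""
    return float(np.quantile(mean_tpm.to_numpy(dtype=float), 1.0 - decile))


def screen_cph(records: list[ProteinRecord], mean_tpm: pd.Series,
               decile: float = 0.10,
               params: TraitParams = TraitParams()) -> list[CPCall]:
    """The CPH candidate filter cascade; records every gene's dropout stage.

    Filters, in order: (1) unannotated, (2) mean TPM at or above the
    (1 - decile) quantile of the whole-transcriptome mean TPM supplied in
    ``mean_tpm`` (which must cover the transcriptome, not just the screened
    records), (3) signal peptide + extracellular, (4) >= 1 CP trait.
    ``dropout_stage`` is the name of the first failed filter, or None for
    accepted candidates (family "CPH").
    """
    cutoff = expression_cutoff(mean_tpm, decile)
    calls = []
    for rec in records:
        if rec.gene_id not in mean_tpm.index:
            raise ValueError(f"no mean TPM for {rec.gene_id!r}")
        if not is_unannotated(rec):
            calls.append(CPCall(rec.gene_id, "none", dropout_stage="annotated"))
            continue
        if float(mean_tpm[rec.gene_id]) < cutoff:
            calls.append(CPCall(rec.gene_id, "none", dropout_stage="expression"))
            continue
        if not (rec.signal_peptide and rec.extracellular):
            calls.append(CPCall(rec.gene_id, "none", dropout_stage="secretion"))
            continue
        traits = trait_scores(rec, params)
        if not traits:
            calls.append(CPCall(rec.gene_id, "none", dropout_stage="traits"))
            continue
        calls.append(CPCall(rec.gene_id, "CPH", traits=traits))
    return calls


def calls_to_frame(calls: list[CPCall]) -> pd.DataFrame:
    """CP calls as a tidy table (traits joined as name:score pairs)."""
    return pd.DataFrame([{
        "gene_id": c.gene_id, "family": c.family, "cbd_count": c.cbd_count,
        "traits": ";".join(f"{k}:{v:.3g}" for k, v in sorted(c.traits.items())),
        "dropout_stage": c.dropout_stage or "",
    } for c in calls])
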