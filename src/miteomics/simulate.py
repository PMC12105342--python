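"""Synthetic data with planted signals for the whole pipeline.

Three generators emulate the statistical structure the analysis assumes:

* :func:`simulate_counts` — negative-binomial RNA-seq counts for a
  larvae/nymphs/females/males design (3 replicates per group by default)
  with planted stage-biased expression profiles;
* :func:`simulate_proteome` — protein FASTA + annotation table with planted
  CPR, CPAP and unannotated trait-bearing (CPH-like) sequences;
* :func:`simulate_blast_hits` — per-taxon-group BLAST tabular hit tables
  with planted non-metazoan donors for the h-index screen.

Every generator is driven by a single integer seed and returns, alongside
its data, a truth table recording what was planted, so downstream recovery
can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import io as mio

DEFAULT_GROUPS = ("larvae", "nymphs", "females", "males")

#: taxon-group vocabulary for the BLAST simulator / HGT screen
TAXON_GROUPS = (
    "invertebrate_non_acari", "fungi", "bacteria", "archaea",
    "protozoa", "viruses",
)
NON_METAZOAN_GROUPS = TAXON_GROUPS[1:]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationConfig:
    """Design of a simulated stage-resolved RNA-seq experiment.

    ``profile_fractions`` maps profile labels to gene fractions. Supported
    labels: ``flat``, ``<group>_up`` for any configured group, and
    ``juvenile_up`` (the first two groups jointly up, matching the
    larvae+nymphs convention). Fractions must sum to <= 1; the remainder
    is flat. ``effect_log2fc`` is the planted log2 fold change applied to
    the up group(s); ``dispersion`` parameterizes the negative binomial as
    variance = mu + mu^2 * dispersion.
    """

    n_genes: int = 2000
    groups: tuple[str, ...] = DEFAULT_GROUPS
    reps_per_group: int = 3
    profile_fractions: dict[str, float] = field(
        default_factory=lambda: {"females_up": 0.10, "males_up": 0.05,
                                 "juvenile_up": 0.05})
    effect_log2fc: float = 3.0
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.reps_per_group <= 0:
            raise ValueError("reps_per_group must be positive")
        if self.effect_log2fc <= 0 or self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("effect_log2fc, baseline_mean, dispersion must be positive")
        total = sum(self.profile_fractions.values())
        if total > 1 + 1e-9:
            raise ValueError(f"profile fractions sum to {total} > 1")
        for label in self.profile_fractions:
            if label != "flat" and label not in self._profile_vocab():
                raise ValueError(f"unknown profile label {label!r}")

    def _profile_vocab(self) -> set[str]:
        vocab = {f"{g}_up" for g in self.groups} | {"flat"}
        if len(self.groups) >= 2:
            vocab.add("juvenile_up")
        return vocab

    def up_groups(self, profile: str) -> tuple[str, ...]:
        """Groups whose mean is multiplied by 2**effect_log2fc."""
        if profile == "flat":
            return ()
        if profile == "juvenile_up":
            return self.groups[:2]
        group = profile.removesuffix("_up")
        return (group,)


class SimulatedCounts(NamedTuple):
    counts: pd.DataFrame      # genes x samples, integer
    lengths: pd.Series        # gene_id -> length_nt
    sample_groups: pd.Series  # sample_id -> group
    truth: pd.DataFrame       # gene_id -> planted_profile


class SimulatedProteome(NamedTuple):
    sequences: dict[str, str]
    annotations: pd.DataFrame  # indexed by gene_id
    truth: pd.DataFrame        # gene_id -> planted_cp_class
    mean_tpm: pd.Series        # gene_id -> whole-culture mean TPM


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # NB with variance mu + mu^2 * d  <=>  n = 1/d, p = n / (n + mu)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_counts(config: SimulationConfig) -> SimulatedCounts:
    """Simulate an integer count matrix with planted stage-biased profiles.

    Per-gene baseline means vary log-normally around ``baseline_mean``;
    genes assigned an ``*_up`` profile have their mean multiplied by
    ``2**effect_log2fc`` in the up group(s). Gene lengths are uniform on
    300-3000 nt. The same seed reproduces the output exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"gene{i:05d}" for i in range(n)]

    profiles = np.array(["flat"] * n, dtype=object)
    cursor = 0
    for label, frac in config.profile_fractions.items():
        count = int(round(frac * n))
        profiles[cursor:cursor + count] = label
        cursor += count
    rng.shuffle(profiles)

    sample_ids = [f"{g}_{r + 1}" for g in config.groups
                  for r in range(config.reps_per_group)]
    sample_groups = pd.Series(
        [g for g in config.groups for _ in range(config.reps_per_group)],
        index=pd.Index(sample_ids, name="sample_id"), name="group")

    baseline = config.baseline_mean * rng.lognormal(0.0, 0.5, size=n)
    effect = 2.0 ** config.effect_log2fc
    mu = np.tile(baseline[:, None], (1, len(sample_ids)))
    group_arr = sample_groups.to_numpy()
    for i, prof in enumerate(profiles):
        ups = config.up_groups(prof)
        if ups:
            mu[i, np.isin(group_arr, ups)] *= effect

    counts = _nb_draw(rng, mu, config.dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=sample_ids)
    lengths = pd.Series(rng.integers(300, 3001, size=n),
                        index=counts_df.index, name="length_nt")
    truth = pd.DataFrame({"planted_profile": profiles}, index=counts_df.index)
    return SimulatedCounts(counts_df, lengths, sample_groups, truth)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _signal_peptide(rng: np.random.Generator) -> str:
    # M + hydrophobic core + small-residue cleavage site; 18 residues total
    core = "".join(rng.choice(np.array(list("AVLIF")), size=16))
    return "M" + core + "A"


# bodies planted with one trait class each; cycled over planted CPH genes
_CPH_TRAIT_CYCLE = ("aap_motifs", "gly_dense", "pvpy_rich")


def _cph_body(rng: np.random.Generator, trait: str) -> str:
    noncys = np.array(list("ADEFGHIKLMNPQRSTVWY"))
    filler = "".join(rng.choice(noncys, size=60))
    if trait == "aap_motifs":
        return filler[:20] + "AAPAAAPVAAPLAAPA" + filler[20:]
    if trait == "gly_dense":
        gly_run = "".join(rng.choice(np.array(list("GGGAP")), size=40))
        return filler[:10] + gly_run + filler[10:40]
    if trait == "pvpy_rich":
        return filler[:15] + "PVPY" * 8 + filler[15:45]
    raise ValueError(trait)


def simulate_proteome(n_background: int = 500, n_cpr: int = 5, n_cpap: int = 5,
                      n_cph: int = 5, seed: int = 0,
                      cbd_counts: tuple[int, ...] | None = None) -> SimulatedProteome:
    """Simulate a proteome with planted cuticular-protein classes.

    CPR proteins carry the IPR000618 domain; CPAP proteins carry 1-7 copies
    of the chitin-binding PF01607 domain (``cbd_counts`` overrides the
    per-protein copy numbers); CPH-like proteins carry no domain/GO/KO or
    in-house annotation, a signal peptide with extracellular localization,
    a mean TPM in the top expression decile and at least one planted
    sequence trait. Background proteins are annotated (GO flag plus a
    non-cuticular domain) so the unannotated filter excludes them.
    """
    for name, v in (("n_background", n_background), ("n_cpr", n_cpr),
                    ("n_cpap", n_cpap), ("n_cph", n_cph)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if cbd_counts is not None and len(cbd_counts) != n_cpap:
        raise ValueError("cbd_counts length must equal n_cpap")
    rng = np.random.default_rng(seed)

    seqs: dict[str, str] = {}
    rows = []
    truth_rows = []
    tpm = {}
    dummy_domains = ("IPR001128", "IPR000719", "PTHR11455", "IPR002290")
    gid_iter = iter(f"prot{i:05d}" for i in range(n_background + n_cpr + n_cpap + n_cph))

    for _ in range(n_background):
        gid = next(gid_iter)
        seqs[gid] = _random_protein(rng, int(rng.integers(100, 400)))
        rows.append({"gene_id": gid,
                     "domain_accessions": str(rng.choice(np.array(dummy_domains))),
                     "go_flag": 1, "ko_flag": int(rng.integers(0, 2)),
                     "inhouse_flags": "", "signal_peptide": int(rng.integers(0, 2)),
                     "sp_cleavage_pos": 0, "extracellular": int(rng.integers(0, 2))})
        truth_rows.append({"gene_id": gid, "planted_cp_class": "none"})
        tpm[gid] = rng.lognormal(np.log(10.0), 1.0)

    for _ in range(n_cpr):
        gid = next(gid_iter)
        seqs[gid] = _random_protein(rng, int(rng.integers(150, 300)))
        rows.append({"gene_id": gid, "domain_accessions": "IPR000618",
                     "go_flag": 1, "ko_flag": 0, "inhouse_flags": "",
                     "signal_peptide": 1, "sp_cleavage_pos": 18,
                     "extracellular": 1})
        truth_rows.append({"gene_id": gid, "planted_cp_class": "CPR"})
        tpm[gid] = rng.lognormal(np.log(50.0), 1.0)

    for j in range(n_cpap):
        gid = next(gid_iter)
        ncbd = cbd_counts[j] if cbd_counts is not None else int(rng.integers(1, 8))
        seqs[gid] = _random_protein(rng, int(rng.integers(150, 300)))
        rows.append({"gene_id": gid,
                     "domain_accessions": ";".join(["PF01607"] * ncbd),
                     "go_flag": 1, "ko_flag": 0, "inhouse_flags": "",
                     "signal_peptide": 1, "sp_cleavage_pos": 18,
                     "extracellular": 1})
        truth_rows.append({"gene_id": gid, "planted_cp_class": "CPAP"})
        tpm[gid] = rng.lognormal(np.log(50.0), 1.0)

    for j in range(n_cph):
        gid = next(gid_iter)
        trait = _CPH_TRAIT_CYCLE[j % len(_CPH_TRAIT_CYCLE)]
        seqs[gid] = _signal_peptide(rng) + _cph_body(rng, trait)
        rows.append({"gene_id": gid, "domain_accessions": "",
                     "go_flag": 0, "ko_flag": 0, "inhouse_flags": "",
                     "signal_peptide": 1, "sp_cleavage_pos": 18,
                     "extracellular": 1})
        truth_rows.append({"gene_id": gid, "planted_cp_class": "CPH"})
        tpm[gid] = float(rng.uniform(500.0, 2000.0))  # safely top decile

    annotations = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["domain_accessions", "go_flag", "ko_flag", "inhouse_flags",
                 "signal_peptide", "sp_cleavage_pos", "extracellular"])
    truth = pd.DataFrame(truth_rows).set_index("gene_id") if truth_rows else \
        pd.DataFrame(columns=["planted_cp_class"])
    mean_tpm = pd.Series(tpm, name="mean_tpm")
    mean_tpm.index.name = "gene_id"
    return SimulatedProteome(seqs, annotations, truth, mean_tpm)


@dataclass
class PlantedHgt:
    """A planted horizontal-transfer event for one gene."""
    donor_group: str
    donor_bitscore: float = 150.0
    invertebrate_bitscore: float = 40.0

    def __post_init__(self) -> None:
        if self.donor_group not in NON_METAZOAN_GROUPS:
            raise ValueError(f"unknown taxon group {self.donor_group!r}")


_FILLER_COLS = {"pident": 50.0, "length": 100, "mismatch": 50, "gapopen": 1,
                "qstart": 1, "qend": 100, "sstart": 1, "send": 100,
                "evalue": 1e-30}


def _hit_row(query: str, subject: str, bitscore: float) -> dict:
    row = {"qseqid": query, "sseqid": subject, **_FILLER_COLS,
           "bitscore": round(float(bitscore), 1)}
    return row


def simulate_blast_hits(protein_ids: list[str],
                        planted: dict[str, PlantedHgt] | None = None,
                        seed: int = 0) -> dict[str, pd.DataFrame]:
    """Simulate per-taxon-group BLAST tabular hit tables.

    Planted genes receive a hit in their donor group at the requested
    bitscore, exceeding their best invertebrate hit; all other genes get an
    invertebrate hit dominating every non-metazoan hit, so their h-index is
    <= 0. Returns a dict of full 12-column outfmt-6 tables keyed by taxon
    group.
    """
    planted = planted or {}
    for gid in planted:
        if gid not in protein_ids:
            raise ValueError(f"planted gene {gid!r} not among protein_ids")
    rng = np.random.default_rng(seed)
    tables: dict[str, list[dict]] = {g: [] for g in TAXON_GROUPS}

    for gid in protein_ids:
        plant = planted.get(gid)
        if plant is not None:
            if plant.invertebrate_bitscore > 0:
                tables["invertebrate_non_acari"].append(
                    _hit_row(gid, f"inv|{gid}", plant.invertebrate_bitscore))
            tables[plant.donor_group].append(
                _hit_row(gid, f"{plant.donor_group}|{gid}", plant.donor_bitscore))
            # weak trace hits in other non-metazoan groups, below invertebrate
            for grp in NON_METAZOAN_GROUPS:
                if grp != plant.donor_group and rng.random() < 0.3:
                    cap = max(plant.invertebrate_bitscore * 0.5, 15.0)
                    tables[grp].append(
                        _hit_row(gid, f"{grp}|{gid}", rng.uniform(10.0, cap)))
        else:
            inv_best = float(rng.uniform(80.0, 300.0))
            tables["invertebrate_non_acari"].append(
                _hit_row(gid, f"inv|{gid}", inv_best))
            for grp in NON_METAZOAN_GROUPS:
                if rng.random() < 0.6:
                    tables[grp].append(
                        _hit_row(gid, f"{grp}|{gid}",
                                 rng.uniform(10.0, inv_best * 0.8)))
    out = {}
    for grp, rows in tables.items():
        df = pd.DataFrame(rows, columns=mio.BLAST6_COLUMNS)
        df.attrs["taxon_group"] = grp
        out[grp] = df
    return out


def write_blast_tables(tables: dict[str, pd.DataFrame], outdir) -> dict[str, Path]:
    """Write each taxon-group table as <group>.blast6.tsv; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for grp, df in tables.items():
        path = outdir / f"{grp}.blast6.tsv"
        df.to_csv(path, sep="\t", header=False, index=False)
        paths[grp] = path
    return paths
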