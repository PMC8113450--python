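"""Synthetic-data generator with recorded ground truth.

Emulates the statistical structure of a mouse Elongator-deficiency study:
a 3-vs-3 DIA proteome with six spike-in peptides, a 6-vs-6 embryonic-brain
transcriptome with a sex covariate, 106-node (40 at desk scale) structural
connectomes with six subjects per group, and LC-MS tRNA-modification peak
areas with pseudouridine as internal standard.  Planted effects tie protein
down-regulation to AA-ending codon content and transcript length, so every
downstream statistic can be checked against truth.

All outputs are deterministic functions of ``SimConfig.seed``: the same
config yields byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .codon import CODON_TO_AA, FAMILIES, SENSE_CODONS, STOP_CODONS
from .config import (INDEPENDENT_MODIFICATIONS, U34_MODIFICATIONS,
                     ConfigError, SimConfig)
from .proteome import PeptideMatrix

AA_ENDING = ("AAA", "CAA", "GAA")
AG_ENDING = ("AAG", "CAG", "GAG")

_STAGE = {"cds": 0, "proteome": 1, "counts": 2, "connectome": 3, "mods": 4}


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STAGE[stage]])


# ---------------------------------------------------------------------------
# coding sequences


def simulate_cds(config: SimConfig, allowed_codons: list[str] | None = None
                 ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate one CDS per gene plus a per-gene truth table.

    Codon usage follows a per-gene Dirichlet model: amino-acid composition
    and within-family synonymous-codon preferences both vary across genes,
    giving a continuum of AA-/AG-ending codon bias.  Every CDS starts with
    ATG, ends with a stop codon, and contains no internal stops.  Truth
    columns: ``length_codons`` (incl. start and stop), ``n_sense`` (sense
    codons only), ``aa_ending_fraction`` and ``ag_ending_fraction``
    (fractions of sense codons; stops excluded), ``log2_length``.

    ``allowed_codons`` restricts sampling to a sense-codon subset (ATG is
    always permitted as the start).
    """
    rng = _rng(config, "cds")
    lo, hi = config.cds_length_range
    sense = list(SENSE_CODONS)
    if allowed_codons is not None:
        bad = set(allowed_codons) - set(SENSE_CODONS)
        if bad:
            raise ConfigError(f"allowed_codons contains non-sense codons: "
                              f"{sorted(bad)}")
        sense = [c for c in SENSE_CODONS if c in set(allowed_codons)]
        if not sense:
            raise ConfigError("allowed_codons leaves no sense codons")
    aas = sorted({CODON_TO_AA[c] for c in sense})
    fam = {aa: [c for c in FAMILIES[aa] if c in sense] for aa in aas}
    stops = sorted(STOP_CODONS)

    records: list[tuple[str, str]] = []
    truth_rows = []
    width = max(4, len(str(max(config.n_genes - 1, 0))))
    for g in range(config.n_genes):
        gene_id = f"gene_{g:0{width}d}"
        length = int(rng.integers(lo, hi + 1))  # codons incl. start + stop
        n_body = max(length - 2, 0)
        # per-gene amino-acid composition and synonymous preferences
        aa_probs = rng.dirichlet(np.full(len(aas), 2.0))
        codon_probs: dict[str, np.ndarray] = {
            aa: rng.dirichlet(np.full(len(fam[aa]), 0.6)) if len(fam[aa]) > 1
            else np.array([1.0])
            for aa in aas
        }
        flat_codons = [c for aa in aas for c in fam[aa]]
        flat_p = np.concatenate([aa_probs[i] * codon_probs[aa]
                                 for i, aa in enumerate(aas)])
        flat_p = flat_p / flat_p.sum()
        body = rng.choice(len(flat_codons), size=n_body, p=flat_p)
        codons = ["ATG"] + [flat_codons[i] for i in body] + \
            [stops[rng.integers(len(stops))]]
        seq = "".join(codons)
        sense_codons = [c for c in codons if c not in STOP_CODONS]
        n_sense = len(sense_codons)
        n_aa = sum(c in AA_ENDING for c in sense_codons)
        n_ag = sum(c in AG_ENDING for c in sense_codons)
        records.append((gene_id, seq))
        truth_rows.append({
            "gene_id": gene_id,
            "length_codons": len(codons),
            "n_sense": n_sense,
            "aa_ending_fraction": n_aa / n_sense,
            "ag_ending_fraction": n_ag / n_sense,
            "log2_length": float(np.log2(len(codons))),
        })
    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "length_codons", "n_sense", "aa_ending_fraction",
        "ag_ending_fraction", "log2_length"])
    return records, truth


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for gene_id, seq in records:
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# proteome


def simulate_proteome(config: SimConfig, cds_truth: pd.DataFrame
                      ) -> tuple[PeptideMatrix, pd.DataFrame]:
    """Simulate the peptide intensity matrix plus per-protein truth.

    Proteins map 1:1 to genes.  Each protein's true log2FC (mutant vs
    control) is ``codon_effect_slope * (AA-fraction - mean) +
    length_effect_slope * (log2 length - mean)``; centring the covariates
    makes the planted effect symmetric, so AA-rich / long proteins go down
    while AA-poor / short proteins go up.  Biological noise is shared by
    all peptides of a protein within a sample; technical noise is
    per-peptide.  Spike-in peptides carry technical noise only and no group
    effect.
    """
    rng = _rng(config, "proteome")
    eff = config.effect_model
    n_mut, n_ctl = config.proteome_design
    if config.n_proteins > len(cds_truth):
        raise ConfigError("n_proteins exceeds the number of simulated genes")

    pick = rng.choice(len(cds_truth), size=config.n_proteins, replace=False)
    pick.sort()
    prot_truth = cds_truth.iloc[pick].reset_index(drop=True).copy()
    aa = prot_truth["aa_ending_fraction"].to_numpy()
    loglen = prot_truth["log2_length"].to_numpy()
    true_fc = (eff.codon_effect_slope * (aa - aa.mean())
               + eff.length_effect_slope * (loglen - loglen.mean()))
    prot_truth["true_log2fc"] = true_fc

    lo, hi = config.peptides_per_protein_range
    n_peps = rng.integers(lo, hi + 1, size=config.n_proteins)
    total_peptides = int(n_peps.sum()) + config.n_spikes
    if config.n_spikes > total_peptides:
        raise ConfigError("n_spikes exceeds the total peptide count")

    samples = [f"mut_{i+1}" for i in range(n_mut)] + \
              [f"ctrl_{i+1}" for i in range(n_ctl)]
    is_mut = np.array([1.0] * n_mut + [0.0] * n_ctl)
    n_samp = len(samples)

    peptide_ids, protein_ids, spike_flags, rows = [], [], [], []
    for p in range(config.n_proteins):
        gene_id = prot_truth.loc[p, "gene_id"]
        bio = rng.normal(0.0, eff.biological_sd, size=n_samp)
        for k in range(int(n_peps[p])):
            baseline = rng.normal(20.0, 2.0)
            tech = rng.normal(0.0, eff.technical_sd, size=n_samp)
            rows.append(baseline + true_fc[p] * is_mut + bio + tech)
            peptide_ids.append(f"{gene_id}_pep{k+1}")
            protein_ids.append(gene_id)
            spike_flags.append(False)
    for s in range(config.n_spikes):
        baseline = rng.normal(18.0, 1.0)
        tech = rng.normal(0.0, eff.technical_sd, size=n_samp)
        rows.append(baseline + tech)
        peptide_ids.append(f"spike_pep{s+1}")
        protein_ids.append(f"spike_{s+1}")
        spike_flags.append(True)

    intensities = pd.DataFrame(np.array(rows), columns=samples,
                               index=pd.Index(peptide_ids, name="peptide_id"))
    design = pd.DataFrame(
        {"group": ["mutant"] * n_mut + ["control"] * n_ctl},
        index=pd.Index(samples, name="sample"))
    matrix = PeptideMatrix(
        intensities=intensities,
        proteins=pd.Series(protein_ids, index=intensities.index,
                           name="protein_id"),
        is_spike=pd.Series(spike_flags, index=intensities.index,
                           name="is_spike"),
        design=design,
    )
    return matrix, prot_truth


# ---------------------------------------------------------------------------
# transcriptome counts + RTS


def simulate_counts_rts(config: SimConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                   pd.DataFrame]:
    """Simulate the RNA-seq count matrix, design, RTS table, and gene truth.

    Counts are negative-binomial with per-sample library-size offsets, an
    optional sex effect on a random gene subset, and planted group log2FCs
    (random sign) on a ``transcript_de_fraction`` subset.  RTS values are
    log-normal and strictly positive.  Returns (counts, design, rts, truth).
    """
    rng = _rng(config, "counts")
    eff = config.effect_model
    n_mut, n_ctl = config.transcriptome_design
    n_samples = n_mut + n_ctl
    samples = [f"mut_{i+1}" for i in range(n_mut)] + \
              [f"ctrl_{i+1}" for i in range(n_ctl)]
    sex = list(config.transcriptome_sex)
    is_mut = np.array([1.0] * n_mut + [0.0] * n_ctl)
    is_male = np.array([1.0 if s == "M" else 0.0 for s in sex])

    n_genes = config.n_genes
    width = max(4, len(str(max(n_genes - 1, 0))))
    gene_ids = [f"gene_{g:0{width}d}" for g in range(n_genes)]

    log_mu = rng.normal(np.log(200.0), 1.0, size=n_genes)
    lib = np.exp(rng.normal(0.0, 0.15, size=n_samples))

    logfc = np.zeros(n_genes)
    n_de = int(round(eff.transcript_de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    logfc[de_idx] = eff.transcript_logfc * rng.choice([-1.0, 1.0], size=n_de)

    sex_fc = np.zeros(n_genes)
    if eff.sex_logfc != 0:
        n_sex = int(round(eff.sex_fraction * n_genes))
        sex_idx = rng.choice(n_genes, size=n_sex, replace=False)
        sex_fc[sex_idx] = eff.sex_logfc

    mu = (np.exp(log_mu)[:, None] * lib[None, :]
          * 2.0 ** (logfc[:, None] * is_mut[None, :]
                    + sex_fc[:, None] * is_male[None, :]))
    phi = eff.nb_dispersion
    counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
    counts_df = pd.DataFrame(counts, columns=samples,
                             index=pd.Index(gene_ids, name="gene_id"))
    design = pd.DataFrame(
        {"group": ["mutant"] * n_mut + ["control"] * n_ctl, "sex": sex},
        index=pd.Index(samples, name="sample"))
    rts = pd.DataFrame({
        "gene_id": gene_ids,
        "rts": np.exp(rng.normal(np.log(0.01), 1.2, size=n_genes)),
    })
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "log2fc": logfc,
        "sex_log2fc": sex_fc,
        "is_null": logfc == 0,
    })
    return counts_df, design, rts, truth


# ---------------------------------------------------------------------------
# connectomes


def simulate_connectomes(config: SimConfig
                         ) -> tuple[dict[str, np.ndarray], pd.DataFrame,
                                    list[str], list[tuple[int, int]]]:
    """Simulate per-subject streamline-count connectivity matrices.

    Edge weights are rounded log-normal streamline counts (nonnegative,
    right-skewed); every matrix is exactly symmetric with a zero diagonal.
    In mutant subjects only, the edges of the planted clique are shifted by
    ``edge_effect`` on the log scale.  Returns (matrices by subject, group
    table, node labels, planted edge list).
    """
    rng = _rng(config, "connectome")
    eff = config.effect_model
    n = config.n_nodes
    n_mut, n_ctl = config.connectome_design
    planted_nodes = sorted(eff.planted_nodes)
    if planted_nodes and planted_nodes[-1] >= n:
        raise ConfigError("planted nodes outside the node range")
    planted_edges = [(a, b) for i, a in enumerate(planted_nodes)
                     for b in planted_nodes[i + 1:]]

    iu = np.triu_indices(n, k=1)
    base_mu = rng.normal(3.0, 1.0, size=iu[0].size)
    planted_mask = np.zeros(iu[0].size, dtype=bool)
    edge_index = {(int(a), int(b)): k
                  for k, (a, b) in enumerate(zip(iu[0], iu[1]))}
    for e in planted_edges:
        planted_mask[edge_index[e]] = True

    subjects = [f"mut_{i+1}" for i in range(n_mut)] + \
               [f"ctrl_{i+1}" for i in range(n_ctl)]
    groups = ["mutant"] * n_mut + ["control"] * n_ctl
    matrices: dict[str, np.ndarray] = {}
    for subj, grp in zip(subjects, groups):
        mu = base_mu.copy()
        if grp == "mutant":
            mu[planted_mask] += eff.edge_effect
        vals = np.round(np.exp(mu + rng.normal(0.0, 0.4, size=mu.size)))
        mat = np.zeros((n, n))
        mat[iu] = vals
        mat = mat + mat.T
        matrices[subj] = mat
    group_table = pd.DataFrame({"subject": subjects, "group": groups})
    node_labels = [f"node_{i:03d}" for i in range(n)]
    return matrices, group_table, node_labels, planted_edges


# ---------------------------------------------------------------------------
# tRNA modifications


def simulate_modifications(config: SimConfig, noise_sd: float = 0.15,
                           genotypes: tuple[str, ...] = ("control", "mutant")
                           ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate LC-MS peak areas per sample with a pseudouridine column.

    Mutant areas are the control level scaled by ``modification_reduction``
    before multiplicative log-normal noise; the internal standard Psi is
    independent of genotype.  Returns (table, truth reduction per
    modification).
    """
    if "control" not in genotypes:
        raise ConfigError("genotypes must include 'control'")
    rng = _rng(config, "mods")
    eff = config.effect_model
    mods = list(U34_MODIFICATIONS) + list(INDEPENDENT_MODIFICATIONS)
    base = {m: float(np.exp(rng.normal(np.log(5000.0), 0.5))) for m in mods}
    psi_base = 50000.0
    rows = []
    for geno in genotypes:
        for i in range(config.n_animals_per_genotype):
            row = {"sample": f"{geno}_{i+1}", "genotype": geno}
            for m in mods:
                level = base[m]
                if geno != "control":
                    level *= eff.modification_reduction.get(m, 1.0)
                row[m] = level * float(np.exp(rng.normal(0.0, noise_sd)))
            row["Psi"] = psi_base * float(np.exp(rng.normal(0.0, noise_sd)))
            rows.append(row)
    table = pd.DataFrame(rows)
    return table, dict(eff.modification_reduction)
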