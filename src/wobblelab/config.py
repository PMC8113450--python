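"""Configuration objects for the synthetic-data generator and pipeline.

A :class:`SimConfig` fully determines every synthetic dataset the toolkit can
produce: a fixed ``seed`` yields byte-identical output files.  The planted
effects (:class:`PlantedEffect`) encode the biological signal the generator
injects — down-regulation of proteins rich in AA-ending codons, a transcript
length effect, a hyper-connected subnetwork, and reduced levels of the
U34-dependent tRNA modifications — so that every downstream statistic has a
recorded ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its invariants."""


#: Elongator-dependent wobble-uridine modifications (reduced in mutants).
U34_MODIFICATIONS = ("ncm5U", "mcm5U", "mcm5s2U")
#: Elongator-independent modifications (unchanged in mutants).
INDEPENDENT_MODIFICATIONS = ("m1A", "m7G", "t6A")


def _default_modification_reduction() -> dict[str, float]:
    red = {m: 0.4 for m in U34_MODIFICATIONS}
    red.update({m: 1.0 for m in INDEPENDENT_MODIFICATIONS})
    return red


@dataclass
class PlantedEffect:
    """Ground-truth effect sizes injected by the generator.

    Parameters
    ----------
    codon_effect_slope:
        log2 fold-change per unit of (centred) AA-ending codon fraction.
        Negative values push AA-rich proteins down in the mutant group.
    length_effect_slope:
        log2 fold-change per (centred) log2 CDS length unit.
    technical_sd:
        Standard deviation (log2 units) of per-peptide technical noise;
        the only variance component spike-in peptides carry.
    biological_sd:
        Standard deviation (log2 units) of per-protein, per-sample
        biological noise shared by all peptides of a protein.
    nb_dispersion:
        Negative-binomial dispersion of the simulated RNA-seq counts.
    transcript_de_fraction / transcript_logfc:
        Fraction of genes given a planted group effect, and its magnitude
        (random sign per gene).
    sex_fraction / sex_logfc:
        Fraction of genes carrying a sex effect, and its magnitude.
    planted_nodes / edge_effect:
        Node set of the hyper-connected clique planted in mutant
        connectomes, and the additive shift (log streamline scale).
    modification_reduction:
        Mutant level as a fraction of the control level, per modification.
    """

    codon_effect_slope: float = -6.0
    length_effect_slope: float = -0.5
    technical_sd: float = 0.1
    biological_sd: float = 0.2
    nb_dispersion: float = 0.1
    transcript_de_fraction: float = 0.1
    transcript_logfc: float = 1.0
    sex_fraction: float = 0.3
    sex_logfc: float = 0.0
    planted_nodes: tuple[int, ...] = tuple(range(8))
    edge_effect: float = 1.4
    modification_reduction: dict[str, float] = field(
        default_factory=_default_modification_reduction
    )

    def __post_init__(self) -> None:
        if self.technical_sd < 0 or self.biological_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigError("negative-binomial dispersion must be > 0")
        for mod, frac in self.modification_reduction.items():
            if not 0 < frac <= 1:
                raise ConfigError(
                    f"modification_reduction[{mod!r}] must lie in (0, 1]"
                )


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults are desk-scale (500 proteins / ~2,500 peptides / 2,000 genes /
    40 connectome nodes); :meth:`study_scale` switches to the sizes of the
    mouse study the generator emulates (2,695 proteins, 12,600 peptides,
    14,266 genes, 106 nodes).
    """

    seed: int = 0
    n_genes: int = 2000
    cds_length_range: tuple[int, int] = (100, 600)
    n_proteins: int = 500
    peptides_per_protein_range: tuple[int, int] = (2, 8)
    n_spikes: int = 6
    proteome_design: tuple[int, int] = (3, 3)  # (mutant, control)
    transcriptome_design: tuple[int, int] = (6, 6)
    # sex label per sample: first the mutant group, then the control group.
    # Deliberately imbalanced (not confounded): embryo cohorts are rarely
    # sex-matched, which is exactly why sex enters the model as a batch term.
    transcriptome_sex: tuple[str, ...] = ("M", "M", "M", "M", "M", "F",
                                          "M", "F", "F", "F", "F", "F")
    n_nodes: int = 40
    connectome_design: tuple[int, int] = (6, 6)
    n_animals_per_genotype: int = 5
    effect_model: PlantedEffect = field(default_factory=PlantedEffect)

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_proteins < 0:
            raise ConfigError("counts must be >= 0")
        lo, hi = self.cds_length_range
        if hi < lo or lo < 1:
            raise ConfigError(
                f"degenerate CDS length range ({lo}, {hi}): need 1 <= min <= max"
            )
        plo, phi = self.peptides_per_protein_range
        if phi < plo or plo < 1:
            raise ConfigError("degenerate peptides-per-protein range")
        for name in ("proteome_design", "transcriptome_design",
                     "connectome_design"):
            sizes = getattr(self, name)
            if any(s < 2 for s in sizes):
                raise ConfigError(f"{name}: group sizes must be >= 2")
        if len(self.transcriptome_sex) != sum(self.transcriptome_design):
            raise ConfigError("transcriptome_sex must label every sample")
        if self.n_nodes < 3:
            raise ConfigError("need at least 3 connectome nodes")
        if self.n_proteins > self.n_genes:
            raise ConfigError("n_proteins cannot exceed n_genes")
        if any(n >= self.n_nodes for n in self.effect_model.planted_nodes):
            raise ConfigError("planted nodes outside the node range")

    @classmethod
    def study_scale(cls, seed: int = 0) -> "SimConfig":
        """Configuration at the sizes of the study being emulated."""
        return cls(
            seed=seed,
            n_genes=14266,
            n_proteins=2695,
            peptides_per_protein_range=(2, 8),
            n_nodes=106,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        data = dict(data)
        effect = data.pop("effect_model", None)
        if effect is not None and not isinstance(effect, PlantedEffect):
            effect = PlantedEffect(**{
                k: tuple(v) if k == "planted_nodes" else v
                for k, v in dict(effect).items()
            })
        for key in ("cds_length_range", "peptides_per_protein_range",
                    "proteome_design", "transcriptome_design",
                    "connectome_design", "transcriptome_sex"):
            if key in data and isinstance(data[key], Sequence):
                data[key] = tuple(data[key])
        if effect is not None:
            data["effect_model"] = effect
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload.get("simulate", payload))
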