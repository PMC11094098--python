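"""Seeded synthetic single-cell count data with planted structure.

Emulates a glioma microenvironment scRNA-seq experiment at desk scale:
several cell populations (e.g. GAMs, tumor cells, lymphocytes) with
planted marker genes, a focal gene (``SORL1`` by default) whose
expression covaries with planted gene programs through a per-cell latent
level, gene-name based mitochondrial/ribosomal/red-blood-cell flags, a
gene-description corpus with planted keywords, and planted
ligand-receptor channels.  Every generator is deterministic given its
seed and returns the matching ground truth so downstream stages can be
tested for parameter recovery.

Counts follow a negative binomial with mean ``mu`` and size ``theta``
(variance ``mu + mu**2/theta``).  The focal-gene model uses a per-cell
latent ``z ~ N(0, 1)``: the focal gene's mean is ``exp(a + b*z)`` and
each program gene's mean is ``baseline * exp(+/- c*z)``, which yields a
monotone association detectable both by rank correlation and by
tree-based feature ranking.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


_DEFAULT_KEYWORDS = (
    "glycolysis",
    "angiogenesis",
    "phagocytosis",
    "inflammation",
    "migration",
    "chemotaxis",
    "hypoxia",
)


@dataclass
class PopulationSpec:
    """One planted cell population.

    Parameters
    ----------
    name
        Population label (used in cell metadata and ground truth).
    n_marker_genes
        Number of genes whose mean is elevated in this population.
    marker_effect
        Fold change applied to marker-gene means inside the population.
    baseline_mean
        Mean counts/cell of a marker gene outside its population.
    keyword
        Planted functional keyword for the population's marker-gene
        documents; assigned from a default list when ``None``.
    """

    name: str
    n_marker_genes: int = 20
    marker_effect: float = 8.0
    baseline_mean: float = 0.5
    keyword: str | None = None


@dataclass
class SynthConfig:
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec("GAMs"),
            PopulationSpec("tumor"),
            PopulationSpec("lymphocytes"),
        ]
    )
    n_cells_per_population: int = 200
    n_noise_genes: int = 1900
    noise_mean: float = 0.5
    nb_dispersion: float = 2.0
    focal_gene_name: str = "SORL1"
    focal_intercept: float = float(np.log(2.0))
    focal_slope: float = 1.0
    n_program_pos: int = 50
    n_program_neg: int = 50
    coupling: float = 0.8
    program_baseline: float = 0.5
    frac_mito: float = 0.05
    frac_ribo: float = 0.10
    frac_rbc: float = 0.002
    n_samples: int = 2
    sample_scale_spread: float = 0.2
    n_planted_channels: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not self.populations:
            raise ConfigError("populations: at least one population required")
        for p in self.populations:
            if p.n_marker_genes <= 0:
                raise ConfigError(f"populations[{p.name}].n_marker_genes: must be > 0")
            if p.marker_effect <= 0:
                raise ConfigError(f"populations[{p.name}].marker_effect: must be > 0")
            if p.baseline_mean <= 0:
                raise ConfigError(f"populations[{p.name}].baseline_mean: must be > 0")
        if self.n_cells_per_population <= 0:
            raise ConfigError("n_cells_per_population: must be > 0")
        if self.n_noise_genes <= 0:
            raise ConfigError("n_noise_genes: must be > 0")
        if not (self.nb_dispersion > 0):
            raise ConfigError("nb_dispersion: must be a positive real")
        if self.n_program_pos < 0 or self.n_program_neg < 0:
            raise ConfigError("n_program_pos/n_program_neg: must be >= 0")
        if not np.isfinite(self.coupling):
            raise ConfigError("coupling: must be finite")
        for name in ("frac_mito", "frac_ribo", "frac_rbc"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}: must be in [0, 1]")
        if self.frac_mito + self.frac_ribo + self.frac_rbc > 1:
            raise ConfigError("frac_mito+frac_ribo+frac_rbc: must sum to <= 1")
        if self.n_samples <= 0:
            raise ConfigError("n_samples: must be > 0")


@dataclass
class PlantedChannel:
    """A planted ligand-receptor communication channel."""

    sender: str
    receiver: str
    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]
    pathway: str

    @property
    def pair_id(self) -> str:
        lig = "+".join(self.ligand_subunits)
        rec = "+".join(self.receptor_subunits)
        return f"{lig}->{rec}"


@dataclass
class GroundTruth:
    cell_population: pd.Series  # cell barcode -> population name
    gene_role: pd.Series  # gene -> marker:<pop> | program_pos | program_neg | focal | noise
    gene_flag: pd.Series  # gene -> mito | ribo | rbc | ""
    keywords: dict[str, str]  # population -> planted keyword
    channels: list[PlantedChannel]
    focal_latent: pd.Series  # cell barcode -> latent z

    def markers_of(self, population: str) -> list[str]:
        return list(self.gene_role.index[self.gene_role == f"marker:{population}"])

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.gene_role.index[self.gene_role == role])

    def to_json(self, path) -> None:
        payload = {
            "cell_population": self.cell_population.to_dict(),
            "gene_role": self.gene_role.to_dict(),
            "gene_flag": self.gene_flag.to_dict(),
            "keywords": self.keywords,
            "channels": [
                {
                    "sender": c.sender,
                    "receiver": c.receiver,
                    "ligand_subunits": list(c.ligand_subunits),
                    "receptor_subunits": list(c.receptor_subunits),
                    "pathway": c.pathway,
                }
                for c in self.channels
            ],
            "focal_latent": {k: float(v) for k, v in self.focal_latent.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            cell_population=pd.Series(d["cell_population"]),
            gene_role=pd.Series(d["gene_role"]),
            gene_flag=pd.Series(d["gene_flag"]),
            keywords=d["keywords"],
            channels=[
                PlantedChannel(
                    c["sender"],
                    c["receiver"],
                    tuple(c["ligand_subunits"]),
                    tuple(c["receptor_subunits"]),
                    c["pathway"],
                )
                for c in d["channels"]
            ],
            focal_latent=pd.Series(d["focal_latent"], dtype=float),
        )


def _gene_names(config: SynthConfig) -> tuple[list[str], pd.Series, pd.Series]:
    """Build the gene list with roles and mito/ribo/rbc flags.

    Flags are carried by real-world naming conventions ("mt-", "Rps"/"Rpl",
    "Hb" prefixes) so the annotation path of the QC stage is exercised.
    """
    names: list[str] = []
    roles: list[str] = []
    for p in config.populations:
        for i in range(p.n_marker_genes):
            names.append(f"{p.name}.mk{i}")
            roles.append(f"marker:{p.name}")
    for i in range(config.n_program_pos):
        names.append(f"ProgPos{i}")
        roles.append("program_pos")
    for i in range(config.n_program_neg):
        names.append(f"ProgNeg{i}")
        roles.append("program_neg")

    n_noise = config.n_noise_genes
    n_mito = int(round(config.frac_mito * n_noise))
    n_ribo = int(round(config.frac_ribo * n_noise))
    n_rbc = int(round(config.frac_rbc * n_noise))
    flags_noise = (
        ["mito"] * n_mito
        + ["ribo"] * n_ribo
        + ["rbc"] * n_rbc
        + [""] * (n_noise - n_mito - n_ribo - n_rbc)
    )
    for i, fl in enumerate(flags_noise):
        if fl == "mito":
            names.append(f"mt-Nd{i}")
        elif fl == "ribo":
            # alternate the two ribosomal-protein prefixes
            names.append(f"Rps{i}" if i % 2 == 0 else f"Rpl{i}")
        elif fl == "rbc":
            names.append(f"Hba{i}")
        else:
            names.append(f"Gene{i}")
        roles.append("noise")

    names.append(config.focal_gene_name)
    roles.append("focal")

    flags = [""] * (len(names) - 1 - n_noise) + flags_noise + [""]
    if len(set(names)) != len(names):
        raise ConfigError("populations: population/gene names collide")
    return names, pd.Series(roles, index=names), pd.Series(flags, index=names)


def generate_dataset(config: SynthConfig | None = None) -> tuple[AnnData, GroundTruth]:
    """Draw a seeded synthetic dataset with planted structure.

    Returns
    -------
    adata
        ``AnnData`` with sparse integer counts (cells x genes), per-cell
        ``obs`` columns ``sample``, ``population`` and per-gene ``var``
        columns ``role``, ``flag``.
    truth
        :class:`GroundTruth` describing every planted feature.
    """
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    names, roles, flags = _gene_names(config)
    n_genes = len(names)
    pops = config.populations
    n_cells = config.n_cells_per_population * len(pops)

    cell_pop = np.repeat([p.name for p in pops], config.n_cells_per_population)
    barcodes = [f"cell{i:05d}" for i in range(n_cells)]
    samples = np.array([f"S{i % config.n_samples}" for i in range(n_cells)])
    # per-sample multiplicative library-size factor (no batch-effect model)
    spread = config.sample_scale_spread
    sample_factor = {
        f"S{i}": 1.0 + spread * (2 * i / max(config.n_samples - 1, 1) - 1)
        for i in range(config.n_samples)
    }
    z = rng.standard_normal(n_cells)

    mu = np.empty((n_genes, n_cells))
    role_arr = roles.to_numpy()
    for gi, (name, role) in enumerate(zip(names, role_arr)):
        if role.startswith("marker:"):
            pop = role.split(":", 1)[1]
            spec = next(p for p in pops if p.name == pop)
            base = np.full(n_cells, spec.baseline_mean)
            base[cell_pop == pop] *= spec.marker_effect
            mu[gi] = base
        elif role == "program_pos":
            mu[gi] = config.program_baseline * np.exp(config.coupling * z)
        elif role == "program_neg":
            mu[gi] = config.program_baseline * np.exp(-config.coupling * z)
        elif role == "focal":
            mu[gi] = np.exp(config.focal_intercept + config.focal_slope * z)
        else:
            mu[gi] = config.noise_mean
    lib = np.array([sample_factor[s] for s in samples])
    mu *= lib[None, :]

    theta = config.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))

    X = sp.csr_matrix(counts.T.astype(np.int32))
    adata = AnnData(
        X=X,
        obs=pd.DataFrame(
            {"sample": samples, "population": cell_pop, "focal_latent": z},
            index=barcodes,
        ),
        var=pd.DataFrame({"role": roles.values, "flag": flags.values}, index=names),
    )

    keywords = {}
    for i, p in enumerate(pops):
        keywords[p.name] = p.keyword or _DEFAULT_KEYWORDS[i % len(_DEFAULT_KEYWORDS)]
    if len(set(keywords.values())) != len(keywords):
        raise ConfigError("populations.keyword: planted keywords must be distinct")

    channels: list[PlantedChannel] = []
    n_ch = min(config.n_planted_channels, max(len(pops) - 1, 0))
    for i in range(n_ch):
        sender, receiver = pops[i], pops[i + 1]
        ligand = (f"{sender.name}.mk0",)
        # alternate single- and two-subunit receptor complexes
        if i % 2 == 1 and receiver.n_marker_genes >= 3:
            receptor = (f"{receiver.name}.mk1", f"{receiver.name}.mk2")
        else:
            receptor = (f"{receiver.name}.mk1",)
        channels.append(
            PlantedChannel(sender.name, receiver.name, ligand, receptor, f"PW{i}")
        )

    truth = GroundTruth(
        cell_population=pd.Series(cell_pop, index=barcodes),
        gene_role=roles,
        gene_flag=flags,
        keywords=keywords,
        channels=channels,
        focal_latent=pd.Series(z, index=barcodes),
    )
    return adata, truth


# ---------------------------------------------------------------------------
# gene-description corpus


@dataclass
class GeneDocCorpus:
    """Bag-of-words documents, one per gene."""

    docs: dict[str, Counter]
    vocabulary: list[str]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for gene, bag in self.docs.items():
                text = " ".join(t for term, n in sorted(bag.items()) for t in [term] * n)
                fh.write(f"{gene}\t{text}\n")

    @classmethod
    def from_tsv(cls, path) -> "GeneDocCorpus":
        docs = {}
        vocab: set[str] = set()
        with open(path) as fh:
            for line in fh:
                gene, _, text = line.rstrip("\n").partition("\t")
                bag = Counter(text.split())
                docs[gene] = bag
                vocab.update(bag)
        return cls(docs=docs, vocabulary=sorted(vocab))


def generate_gene_docs(
    truth: GroundTruth,
    vocab_size: int = 2000,
    words_per_doc: int = 40,
    keyword_rate: float = 0.3,
    seed: int = 0,
) -> GeneDocCorpus:
    """Generate a synthetic gene-description corpus.

    Each gene becomes a bag of words.  Marker genes of population *p*
    emit that population's planted keyword at rate ``keyword_rate`` and
    otherwise draw uniformly from the shared vocabulary; all other genes
    draw uniformly from the shared vocabulary.
    """
    kw = list(dict.fromkeys(truth.keywords.values()))
    if vocab_size < len(kw):
        raise ConfigError(
            f"vocab_size: {vocab_size} smaller than number of planted keywords ({len(kw)})"
        )
    if words_per_doc < 0:
        raise ConfigError("words_per_doc: must be >= 0")
    vocab = kw + [f"term{i:04d}" for i in range(vocab_size - len(kw))]
    rng = np.random.default_rng(seed)

    docs: dict[str, Counter] = {}
    for gene, role in truth.gene_role.items():
        if words_per_doc == 0:
            docs[gene] = Counter()
            continue
        draws = rng.integers(0, vocab_size, size=words_per_doc)
        words = [vocab[i] for i in draws]
        if role.startswith("marker:"):
            pop_kw = truth.keywords[role.split(":", 1)[1]]
            mask = rng.random(words_per_doc) < keyword_rate
            words = [pop_kw if m else w for w, m in zip(words, mask)]
        docs[gene] = Counter(words)
    return GeneDocCorpus(docs=docs, vocabulary=vocab)


def generate_lr_database(
    truth: GroundTruth, n_decoys: int = 8, seed: int = 0
) -> pd.DataFrame:
    """Ligand-receptor database holding the planted channels plus decoys.

    Decoy pairs are drawn from noise genes (never mito/ribo/rbc-flagged),
    each in its own singleton pathway.  Columns: ``pair``,
    ``ligand_subunits`` and ``receptor_subunits`` (';'-joined),
    ``pathway``.
    """
    rows = []
    for c in truth.channels:
        rows.append(
            {
                "pair": c.pair_id,
                "ligand_subunits": ";".join(c.ligand_subunits),
                "receptor_subunits": ";".join(c.receptor_subunits),
                "pathway": c.pathway,
            }
        )
    noise = [
        g
        for g in truth.genes_with_role("noise")
        if truth.gene_flag[g] == ""
    ]
    if n_decoys > 0:
        if len(noise) < 2 * n_decoys:
            raise ConfigError("n_decoys: not enough noise genes for decoy pairs")
        rng = np.random.default_rng(seed)
        picks = rng.choice(len(noise), size=2 * n_decoys, replace=False)
        for i in range(n_decoys):
            lig, rec = noise[picks[2 * i]], noise[picks[2 * i + 1]]
            rows.append(
                {
                    "pair": f"{lig}->{rec}",
                    "ligand_subunits": lig,
                    "receptor_subunits": rec,
                    "pathway": f"decoyPW{i}",
                }
            )
    return pd.DataFrame(rows, columns=["pair", "ligand_subunits", "receptor_subunits", "pathway"])
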