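"""Core data containers shared across the pipeline stages.

Matrices are held as :class:`pandas.DataFrame` objects with transcription
factors (TFs) on the rows and target genes (TGs) on the columns; tabular
records (motif hits, differential-expression calls, ranked predictions) are
plain DataFrames with a documented column contract.  The dataclasses here
bundle the pieces that always travel together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Evidence source classes, ordered by increasing certainty of the
#: TF-target relationship they confer.
SOURCE_CLASSES = (
    "computational",
    "high-throughput",
    "multi-source",
    "direct-experimental",
)

#: Region classes a motif hit can fall in: an evolutionarily conserved
#: region scanned 3 kb upstream of the TSS, or the proximal promoter
#: window (-1000..+200 around the TSS).
REGION_CLASSES = ("ECR", "proximal")


class ConfigurationError(ValueError):
    """Raised when a synthetic-data configuration is internally inconsistent."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic benchmark generator.

    The defaults describe a small perturbation-array compendium: one
    knockout-style experiment per TF with a few replicates per group,
    planted co-regulated modules whose genes respond coherently to the
    perturbation of their regulator, and four partially informative
    evidence layers on top.

    Parameters
    ----------
    n_genes:
        Number of non-TF genes on the array.
    n_tfs:
        Number of transcription factors; each TF owns one regulatory
        module and is perturbed in exactly one experiment.
    module_size:
        Number of target genes per regulatory module.
    n_experiments:
        Number of two-group experiments; the first ``n_tfs`` perturb one
        TF each, any surplus experiments are nulls.
    replicates_per_group:
        Array replicates in each of the mutant and control groups.
    effect_size:
        Log2 shift applied to a perturbed TF and its targets in the
        mutant group.
    noise_sd:
        Within-group standard deviation on the log2 scale.
    present_rate:
        Probability that a measurement carries a Present detection flag.
    term_universe:
        Number of annotation terms in the catalog.
    terms_per_module:
        Number of module-specific annotation terms.
    p_shared_term:
        Probability a module gene is annotated to each of its module's terms.
    p_term_bg:
        Probability of annotation to any non-module term.
    p_motif_true:
        Probability a true target's promoter carries a conserved hit of
        its regulator's motif.
    p_motif_bg:
        Background probability of a conserved motif hit.
    n_decoy_motifs:
        Motif families in the vocabulary with no planted targets.
    p_evidence:
        Probability a true edge has a curated interaction record.
    mean_cocitations:
        Mean of the geometric co-citation count distribution.
    seed:
        Seed for all randomness in the generators.
    """

    n_genes: int = 200
    n_tfs: int = 6
    module_size: int = 12
    n_experiments: int = 6
    replicates_per_group: int = 3
    effect_size: float = 1.0
    noise_sd: float = 0.25
    present_rate: float = 0.9
    term_universe: int = 60
    terms_per_module: int = 5
    p_shared_term: float = 0.8
    p_term_bg: float = 0.03
    p_motif_true: float = 0.8
    p_motif_bg: float = 0.1
    n_decoy_motifs: int = 6
    p_evidence: float = 0.3
    mean_cocitations: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_tfs": self.n_tfs,
            "module_size": self.module_size,
            "n_experiments": self.n_experiments,
            "replicates_per_group": self.replicates_per_group,
            "term_universe": self.term_universe,
            "terms_per_module": self.terms_per_module,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        probs = {
            "present_rate": self.present_rate,
            "p_shared_term": self.p_shared_term,
            "p_term_bg": self.p_term_bg,
            "p_motif_true": self.p_motif_true,
            "p_motif_bg": self.p_motif_bg,
            "p_evidence": self.p_evidence,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        if self.n_tfs * self.module_size > self.n_genes:
            raise ConfigurationError(
                "n_tfs * module_size exceeds n_genes; modules must fit in the gene set"
            )
        if self.n_experiments < self.n_tfs:
            raise ConfigurationError("need at least one experiment per TF")
        if self.replicates_per_group < 2:
            raise ConfigurationError(
                "replicates_per_group must be >= 2 (two-sample t-test undefined otherwise)"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.p_motif_true < self.p_motif_bg:
            raise ConfigurationError(
                "p_motif_true must be >= p_motif_bg for a recoverable network"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruthNetwork:
    """Planted regulatory structure behind a synthetic dataset."""

    tfs: list[str]
    genes: list[str]
    modules: dict[str, list[str]]
    module_tf: dict[str, str]
    edges: set[tuple[str, str]]
    motif_of: dict[str, str]

    def targets_of(self, tf: str) -> set[str]:
        return {g for t, g in self.edges if t == tf}

    @property
    def module_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.modules.values():
            out.update(members)
        return out


@dataclass
class ExpressionDataset:
    """Normalized log2 expression values with design and Present flags.

    ``values`` and ``present`` are gene x sample frames over identical
    axes; ``design`` is indexed by sample with columns ``experiment`` and
    ``group`` (``mutant`` / ``control``).
    """

    values: pd.DataFrame
    design: pd.DataFrame
    present: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.present.columns) or not self.values.index.equals(
            self.present.index
        ):
            raise ValueError("values and present flags must share both axes")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)[:5]}")
        if not self.values.index.is_unique:
            raise ValueError("gene identifiers must be unique")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def experiments(self) -> list[str]:
        return list(pd.unique(self.design["experiment"]))

    def samples_of(self, experiment: str, group: str | None = None) -> list[str]:
        mask = self.design["experiment"] == experiment
        if group is not None:
            mask &= self.design["group"] == group
        return list(self.design.index[mask])


@dataclass(frozen=True)
class EvidenceRecord:
    """One curated interaction-evidence record for a TF-gene pair."""

    tf: str
    gene: str
    source_class: str
    co_citations: int = 0
    provenance: str | None = None

    def __post_init__(self) -> None:
        if self.source_class not in SOURCE_CLASSES:
            raise ValueError(
                f"unknown source class {self.source_class!r}; expected one of {SOURCE_CLASSES}"
            )
        if self.co_citations < 0 or int(self.co_citations) != self.co_citations:
            raise ValueError("co_citations must be a non-negative integer")


class AnnotationCatalog:
    """Term -> gene-set catalog (GMT-style) with a reverse index."""

    def __init__(self, terms: Mapping[str, Sequence[str]]):
        self.terms: dict[str, frozenset[str]] = {
            t: frozenset(gs) for t, gs in terms.items() if len(gs) > 0
        }
        self._gene_terms: dict[str, set[str]] = {}
        for term, genes in self.terms.items():
            for g in genes:
                self._gene_terms.setdefault(g, set()).add(term)

    @property
    def universe(self) -> set[str]:
        """All annotated genes."""
        return set(self._gene_terms)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def terms_of(self, gene: str) -> frozenset[str]:
        return frozenset(self._gene_terms.get(gene, frozenset()))

    def genes_of(self, term: str) -> frozenset[str]:
        return self.terms.get(term, frozenset())

    def __len__(self) -> int:
        return len(self.terms)

    def __bool__(self) -> bool:
        return bool(self.terms)
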