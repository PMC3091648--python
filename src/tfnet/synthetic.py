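"""Seeded generators for synthetic perturbation-array benchmarks.

The generators plant a known TF -> target-gene network and emit the five
inputs the inference pipeline consumes: a two-group expression compendium
in which each TF's module responds to its perturbation, an annotation
catalog in which co-regulated genes share terms, a promoter motif-hit
table enriched for the true regulator's motif among its targets, curated
interaction-evidence records covering a subset of true edges, and the
motif-family -> TF map.  Everything is deterministic for a fixed
:class:`~tfnet.containers.SyntheticConfig` (the seed is part of it).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    AnnotationCatalog,
    ConfigurationError,
    EvidenceRecord,
    ExpressionDataset,
    GroundTruthNetwork,
    SOURCE_CLASSES,
    SyntheticConfig,
)

# Sub-seeds keep the five generators independent of one another while all
# deriving from the single config seed.
_STREAMS = {"truth": 1, "expression": 2, "annotation": 3, "motifs": 4, "evidence": 5}


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STREAMS[stream]]))


def generate_ground_truth(config: SyntheticConfig) -> GroundTruthNetwork:
    """Plant one regulatory module per TF and enumerate the true edges."""
    config.validate()
    rng = _rng(config, "truth")
    tfs = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    member_ids = rng.permutation(config.n_genes)[: config.n_tfs * config.module_size]
    modules: dict[str, list[str]] = {}
    module_tf: dict[str, str] = {}
    edges: set[tuple[str, str]] = set()
    for i, tf in enumerate(tfs):
        block = sorted(member_ids[i * config.module_size : (i + 1) * config.module_size])
        mod_id = f"M{i + 1:02d}"
        modules[mod_id] = [genes[j] for j in block]
        module_tf[mod_id] = tf
        edges.update((tf, genes[j]) for j in block)
    motif_of = {tf: f"MOT_{tf}" for tf in tfs}
    return GroundTruthNetwork(
        tfs=tfs, genes=genes, modules=modules, module_tf=module_tf, edges=edges, motif_of=motif_of
    )


def _experiment_names(config: SyntheticConfig) -> list[str]:
    return [f"E{i + 1:02d}" for i in range(config.n_experiments)]


def simulate_expression_dataset(
    truth: GroundTruthNetwork, config: SyntheticConfig
) -> ExpressionDataset:
    """Simulate the log2 expression compendium.

    One experiment per TF: in the mutant group the perturbed TF and the
    genes of its module are shifted down by ``effect_size`` (a knockout
    lowers its direct targets); every other gene has equal expectation in
    the two groups.  Experiments beyond ``n_tfs`` are nulls.
    """
    config.validate()
    if config.replicates_per_group < 2:
        raise ConfigurationError("replicates_per_group must be >= 2 for a two-sample t-test")
    rng = _rng(config, "expression")
    row_ids = truth.tfs + truth.genes
    baseline = rng.normal(8.0, 1.0, size=len(row_ids))

    experiments = _experiment_names(config)
    sample_names: list[str] = []
    design_rows: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    for e_idx, exp in enumerate(experiments):
        perturbed_tf = truth.tfs[e_idx] if e_idx < len(truth.tfs) else None
        shifted = np.zeros(len(row_ids))
        if perturbed_tf is not None:
            affected = {perturbed_tf} | truth.targets_of(perturbed_tf)
            mask = np.array([r in affected for r in row_ids])
            shifted[mask] = -config.effect_size
        for group in ("control", "mutant"):
            for rep in range(config.replicates_per_group):
                mean = baseline + (shifted if group == "mutant" else 0.0)
                columns.append(mean + rng.normal(0.0, config.noise_sd, size=len(row_ids)))
                sample_names.append(f"{exp}_{group[:3]}_{rep + 1}")
                design_rows.append((exp, group))
    values = pd.DataFrame(np.column_stack(columns), index=row_ids, columns=sample_names)
    design = pd.DataFrame(design_rows, index=sample_names, columns=["experiment", "group"])
    present = pd.DataFrame(
        rng.random(values.shape) < config.present_rate,
        index=values.index,
        columns=values.columns,
    )
    return ExpressionDataset(values=values, design=design, present=present)


def generate_annotation_catalog(
    truth: GroundTruthNetwork, config: SyntheticConfig
) -> AnnotationCatalog:
    """Build a term catalog in which co-module genes share annotations.

    Each module (TF included) draws its members into a dedicated block of
    ``terms_per_module`` terms with probability ``p_shared_term``; every
    gene is annotated to the remaining terms independently with the
    background probability ``p_term_bg``.
    """
    config.validate()
    if config.term_universe < 10:
        raise ConfigurationError("term_universe must be >= 10")
    n_module_terms = len(truth.modules) * config.terms_per_module
    if n_module_terms > config.term_universe:
        raise ConfigurationError("term_universe too small for the module-specific term blocks")
    rng = _rng(config, "annotation")
    all_ids = truth.tfs + truth.genes
    if not all_ids:
        return AnnotationCatalog({})
    term_names = [f"T{i + 1:04d}" for i in range(config.term_universe)]
    term_genes: dict[str, set[str]] = {t: set() for t in term_names}

    for m_idx, (mod_id, members) in enumerate(sorted(truth.modules.items())):
        block = term_names[m_idx * config.terms_per_module : (m_idx + 1) * config.terms_per_module]
        annotated = list(members) + [truth.module_tf[mod_id]]
        for term in block:
            for g in annotated:
                if rng.random() < config.p_shared_term:
                    term_genes[term].add(g)
    module_of: dict[str, int] = {}
    for m_idx, (mod_id, members) in enumerate(sorted(truth.modules.items())):
        for g in list(members) + [truth.module_tf[mod_id]]:
            module_of[g] = m_idx
    for t_idx, term in enumerate(term_names):
        owner = t_idx // config.terms_per_module if t_idx < n_module_terms else -1
        for g in all_ids:
            if module_of.get(g, -2) == owner:
                continue  # module block handled above
            if rng.random() < config.p_term_bg:
                term_genes[term].add(g)
    return AnnotationCatalog({t: sorted(gs) for t, gs in term_genes.items() if gs})


def motif_vocabulary(truth: GroundTruthNetwork, config: SyntheticConfig) -> list[str]:
    """True regulator motif families plus decoy families with no targets."""
    decoys = [f"MOT_DEC{i + 1:02d}" for i in range(config.n_decoy_motifs)]
    return [truth.motif_of[tf] for tf in truth.tfs] + decoys


def generate_motif_hits(truth: GroundTruthNetwork, config: SyntheticConfig) -> pd.DataFrame:
    """Emit a conserved promoter motif-hit table.

    A true target carries at least one conserved hit of its regulator's
    motif with probability ``p_motif_true``; any other (motif, gene)
    combination with probability ``p_motif_bg``.  Hit counts are
    ``1 + Poisson(0.7)`` so single and multiple occurrences both arise,
    and each hit is placed in the proximal window (-1000..+200) or the
    upstream conserved-region window (-3000..0).
    """
    config.validate()
    rng = _rng(config, "motifs")
    motifs = motif_vocabulary(truth, config)
    motif_targets = {
        truth.motif_of[tf]: truth.targets_of(tf) for tf in truth.tfs
    }
    all_ids = truth.tfs + truth.genes
    rows: list[tuple[str, str, int, str, bool]] = []
    for motif in motifs:
        targets = motif_targets.get(motif, set())
        for gene in all_ids:
            p = config.p_motif_true if gene in targets else config.p_motif_bg
            if rng.random() >= p:
                continue
            n_hits = 1 + rng.poisson(0.7)
            for _ in range(n_hits):
                if rng.random() < 0.6:
                    region, pos = "proximal", int(rng.integers(-1000, 200))
                else:
                    region, pos = "ECR", int(rng.integers(-3000, 0))
                rows.append((gene, motif, pos, region, True))
    return pd.DataFrame(
        rows, columns=["gene", "motif", "position", "region_class", "conserved"]
    )


def generate_interaction_evidence(
    truth: GroundTruthNetwork, config: SyntheticConfig
) -> list[EvidenceRecord]:
    """Curated-evidence records covering a random subset of true edges.

    Source classes are drawn over the four-level vocabulary and the
    co-citation count is geometric with mean ``mean_cocitations`` so that
    both the <=10 and >=10 branches of the interaction score occur.
    """
    config.validate()
    rng = _rng(config, "evidence")
    records: list[EvidenceRecord] = []
    databases = ("DB_alpha", "DB_beta", "DB_gamma")
    class_probs = (0.35, 0.35, 0.15, 0.15)
    for tf, gene in sorted(truth.edges):
        if rng.random() >= config.p_evidence:
            continue
        source = SOURCE_CLASSES[rng.choice(len(SOURCE_CLASSES), p=class_probs)]
        cocite = int(rng.geometric(1.0 / max(config.mean_cocitations, 1.0)) - 1)
        records.append(
            EvidenceRecord(
                tf=tf,
                gene=gene,
                source_class=source,
                co_citations=cocite,
                provenance=databases[int(rng.integers(len(databases)))],
            )
        )
    return records


def motif_tf_map(truth: GroundTruthNetwork) -> dict[str, list[str]]:
    """Motif family -> member TF genes (the reporting-time expansion map)."""
    out: dict[str, list[str]] = {}
    for tf, motif in truth.motif_of.items():
        out.setdefault(motif, []).append(tf)
    return {m: sorted(tfs) for m, tfs in out.items()}


def simulate_deletion_experiment(
    truth: GroundTruthNetwork,
    config: SyntheticConfig,
    tf: str,
    seed: int,
) -> ExpressionDataset:
    """Simulate one fresh, held-out deletion array for ``tf``.

    Used for overlap validation: the experiment is generated from a seed
    independent of the training compendium, with the same noise model and
    the TF's targets shifted down by ``effect_size`` in the mutant group.
    """
    if tf not in truth.tfs:
        raise ValueError(f"unknown TF {tf!r}")
    single = SyntheticConfig(**{**config.to_dict(), "seed": seed})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    row_ids = truth.tfs + truth.genes
    baseline = rng.normal(8.0, 1.0, size=len(row_ids))
    affected = {tf} | truth.targets_of(tf)
    mask = np.array([r in affected for r in row_ids])
    columns, names, design_rows = [], [], []
    for group in ("control", "mutant"):
        shift = np.where(mask, -single.effect_size, 0.0) if group == "mutant" else 0.0
        for rep in range(single.replicates_per_group):
            columns.append(baseline + shift + rng.normal(0.0, single.noise_sd, len(row_ids)))
            names.append(f"DEL_{group[:3]}_{rep + 1}")
            design_rows.append(("DEL", group))
    values = pd.DataFrame(np.column_stack(columns), index=row_ids, columns=names)
    design = pd.DataFrame(design_rows, index=names, columns=["experiment", "group"])
    present = pd.DataFrame(True, index=values.index, columns=values.columns)
    return ExpressionDataset(values=values, design=design, present=present)
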