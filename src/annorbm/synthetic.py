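"""Synthetic ontologies and annotation matrices with planted structure.

The generator emulates the regime annotation-completion methods face: a
DAG-structured label space, true-path-consistent binary annotations driven
by latent functional modules shared across proteins, and a masking process
standing in for annotation incompleteness.  Because masked annotations are
implied by modules shared with other proteins, they carry a genuine
statistical signal that a competent model can recover — this is the engine
of the offline test bed.

Masking operates on each protein's most-specific annotated terms (the terms
with no annotated child for that protein), then prunes ancestors supported
only by masked terms, so the training matrix stays true-path closed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, asdict

import numpy as np

from .annotations import AnnotationMatrix, TemporalSplit
from .errors import GenerationError, ValidationError
from .ontology import GODag, GOTerm

logger = logging.getLogger(__name__)

_MAX_RETRIES = 100


@dataclass
class SyntheticSpec:
    """Parameters of the planted-module generator.

    ``n_modules`` latent modules each own ``terms_per_module`` leaf-ward
    terms; a protein joins each module independently with probability
    ``module_prob`` and is annotated with the union of its modules' terms
    (plus rare spurious leaves at ``noise_rate``), closed under ancestors.
    ``mask_rate`` is the per-term probability that a most-specific
    annotation is hidden from the training snapshot.
    """

    n_terms: int = 200
    n_proteins: int = 500
    n_modules: int = 10
    module_prob: float = 0.2
    terms_per_module: int = 5
    dag_parent_mean: float = 1.5
    noise_rate: float = 0.01
    mask_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 2 or self.n_proteins < 1 or self.n_modules < 1:
            raise ValidationError("counts must be positive (n_terms >= 2)")
        if self.terms_per_module < 1:
            raise ValidationError("terms_per_module must be >= 1")
        if not 0 < self.module_prob < 1:
            raise ValidationError("module_prob must be in (0, 1)")
        if self.dag_parent_mean <= 0:
            raise ValidationError("dag_parent_mean must be positive")
        if not 0 <= self.noise_rate < 1:
            raise ValidationError("noise_rate must be in [0, 1)")
        if not 0 <= self.mask_rate < 1:
            raise ValidationError("mask_rate must be in [0, 1)")


def _accession(i: int) -> str:
    return f"GO:{i:07d}"


def generate_dag(spec: SyntheticSpec) -> GODag:
    """A single-rooted random DAG, acyclic by construction.

    Terms are added in topological order; each non-root term draws
    ``max(1, Poisson(dag_parent_mean))`` parents uniformly from the earlier
    terms.  All terms share the biological_process namespace.
    """
    rng = np.random.default_rng(spec.seed)
    terms: dict[str, GOTerm] = {}
    ids = [_accession(i + 1) for i in range(spec.n_terms)]
    terms[ids[0]] = GOTerm(id=ids[0], name="synthetic root")
    for i in range(1, spec.n_terms):
        k = min(i, max(1, int(rng.poisson(spec.dag_parent_mean))))
        parents = rng.choice(i, size=k, replace=False)
        terms[ids[i]] = GOTerm(
            id=ids[i],
            name=f"synthetic term {i}",
            parents={ids[int(p)] for p in parents},
        )
    return GODag(terms)


def _leaf_terms(dag: GODag) -> list[str]:
    return sorted(t for t in dag.active_terms() if not dag.children(t))


def _closure_row(specific: set[str], dag: GODag, term_ix: dict[str, int], n_terms: int):
    row = np.zeros(n_terms, dtype=np.int8)
    for t in specific:
        row[term_ix[t]] = 1
        for anc in dag.ancestors(t):
            row[term_ix[anc]] = 1
    return row


def generate_annotations(
    dag: GODag, spec: SyntheticSpec
) -> tuple[AnnotationMatrix, dict[str, frozenset[int]]]:
    """Planted-module annotations, true-path closed.

    Returns the full (complete) annotation matrix and the protein-to-module
    assignment map.  Proteins drawing no annotation are redrawn a bounded
    number of times.
    """
    rng = np.random.default_rng(spec.seed + 1)
    terms = dag.active_terms()
    term_ix = {t: j for j, t in enumerate(terms)}
    leaves = _leaf_terms(dag)
    pool = leaves if len(leaves) >= spec.terms_per_module else [
        t for t in terms if t not in dag.roots
    ]
    module_terms = [
        set(rng.choice(pool, size=min(spec.terms_per_module, len(pool)), replace=False))
        for _ in range(spec.n_modules)
    ]

    proteins = [f"P{i + 1:05d}" for i in range(spec.n_proteins)]
    values = np.zeros((spec.n_proteins, len(terms)), dtype=np.int8)
    memberships: dict[str, frozenset[int]] = {}
    for i, prot in enumerate(proteins):
        for attempt in range(_MAX_RETRIES):
            joined = frozenset(
                k for k in range(spec.n_modules) if rng.random() < spec.module_prob
            )
            specific: set[str] = set()
            for k in joined:
                specific |= module_terms[k]
            for leaf in leaves:
                if rng.random() < spec.noise_rate:
                    specific.add(leaf)
            if specific:
                break
        else:
            raise GenerationError(
                f"protein {prot} drew no annotations after {_MAX_RETRIES} "
                "attempts; increase module_prob or noise_rate"
            )
        memberships[prot] = joined
        values[i] = _closure_row(specific, dag, term_ix, len(terms))
    return AnnotationMatrix(proteins, terms, values), memberships


def _most_specific(row: np.ndarray, dag: GODag, terms: list[str], term_ix) -> list[str]:
    """Annotated terms with no annotated child for this protein."""
    out = []
    for j in np.nonzero(row)[0]:
        t = terms[j]
        if not any(row[term_ix[c]] for c in dag.children(t) if c in term_ix):
            out.append(t)
    return out


def mask_annotations(
    full: AnnotationMatrix, dag: GODag, spec: SyntheticSpec
) -> TemporalSplit:
    """Hide a fraction of most-specific annotations to form a training snapshot.

    Each most-specific annotated term of each protein is masked with
    probability ``mask_rate``; the training row is then the ancestor closure
    of the surviving most-specific terms, so ancestors supported only by
    masked terms disappear too.  Removed pairs are the evaluation positives;
    pairs absent from the full matrix are the negatives.  A protein that
    would lose all annotations has its masking resampled.
    """
    rng = np.random.default_rng(spec.seed + 2)
    terms = full.terms
    term_ix = {t: j for j, t in enumerate(terms)}
    train_values = np.zeros_like(full.values)
    for i in range(full.shape[0]):
        row = full.values[i]
        specific = _most_specific(row, dag, terms, term_ix)
        for attempt in range(_MAX_RETRIES):
            kept = [t for t in specific if rng.random() >= spec.mask_rate]
            if kept or spec.mask_rate == 0:
                break
        else:
            raise GenerationError(
                f"protein {full.proteins[i]} lost all annotations in every "
                f"of {_MAX_RETRIES} masking draws"
            )
        train_values[i] = _closure_row(set(kept), dag, term_ix, len(terms))

    train = full.with_values(train_values)
    removed_r, removed_c = np.nonzero((full.values == 1) & (train_values == 0))
    eval_positives = {
        (full.proteins[i], terms[j])
        for i, j in zip(removed_r.tolist(), removed_c.tolist())
    }
    neg_r, neg_c = np.nonzero(full.values == 0)
    eval_negatives = {
        (full.proteins[i], terms[j]) for i, j in zip(neg_r.tolist(), neg_c.tolist())
    }
    return TemporalSplit(train, eval_positives, eval_negatives)


def generate(spec: SyntheticSpec):
    """Convenience wrapper: DAG, full matrix, module map and temporal split."""
    dag = generate_dag(spec)
    full, modules = generate_annotations(dag, spec)
    split = mask_annotations(full, dag, spec)
    return dag, full, modules, split


# ---------------------------------------------------------------------------
# Flat-file export (OBO + GAF) so the full parse-train-evaluate path runs
# end-to-end on generated data.
# ---------------------------------------------------------------------------


def write_obo(dag: GODag, path) -> None:
    """Write the DAG as a minimal OBO 1.2 file."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for acc in sorted(dag.terms):
            term = dag.terms[acc]
            fh.write(f"\n[Term]\nid: {term.id}\nname: {term.name}\n")
            fh.write(f"namespace: {term.namespace}\n")
            if term.obsolete:
                fh.write("is_obsolete: true\n")
            for parent in sorted(term.parents):
                fh.write(f"is_a: {parent}\n")


def write_gaf(matrix: AnnotationMatrix, dag: GODag, path) -> None:
    """Write a matrix's most-specific annotations as a GAF 2.1 file.

    Only most-specific terms are written (evidence code EXP); parsing the
    file back and re-closing under ancestors reproduces the matrix.
    """
    terms = matrix.terms
    term_ix = {t: j for j, t in enumerate(terms)}
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for i, prot in enumerate(matrix.proteins):
            for t in _most_specific(matrix.values[i], dag, terms, term_ix):
                ns = dag.namespace_of(t)
                aspect = {"biological_process": "P", "cellular_component": "C",
                          "molecular_function": "F"}[ns]
                fields = [
                    "SYN", prot, prot, "", t, "SYN:0000001", "EXP", "",
                    aspect, "", "", "protein", "taxon:0", "20150101", "SYN",
                    "", "",
                ]
                fh.write("\t".join(fields) + "\n")


def write_dataset(spec: SyntheticSpec, outdir) -> dict[str, str]:
    """Write OBO, full and training GAF snapshots, and a metadata JSON.

    Returns the mapping of artifact name to file path.  Byte-identical for
    identical specs (seed included).
    """
    dag, full, modules, split = generate(spec)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "obo": os.path.join(outdir, "ontology.obo"),
        "gaf_train": os.path.join(outdir, "annotations_train.gaf"),
        "gaf_full": os.path.join(outdir, "annotations_full.gaf"),
        "meta": os.path.join(outdir, "meta.json"),
    }
    write_obo(dag, paths["obo"])
    write_gaf(split.train, dag, paths["gaf_train"])
    write_gaf(full, dag, paths["gaf_full"])
    with open(paths["meta"], "w") as fh:
        json.dump(
            {
                "spec": asdict(spec),
                "modules": {p: sorted(m) for p, m in modules.items()},
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths
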