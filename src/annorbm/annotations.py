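"""GAF annotation parsing and the binary protein x term association matrix.

Annotations arrive as GAF 2.x tab-separated files.  Records are filtered by
evidence code (IEA — annotations inferred electronically — is excluded by
default to avoid circular prediction), turned into a binary matrix, closed
under the true-path rule and filtered.  A temporal train/validation split
pairs an older annotation snapshot with a newer one: pairs that are absent
in the older snapshot but present in the newer one are the evaluation
positives.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .ontology import GODag, NAMESPACE_ALIASES, filter_terms, propagate_true_path

logger = logging.getLogger(__name__)

_EVIDENCE_RE = re.compile(r"^[A-Z]{2,3}$")

#: Evidence codes excluded by default (electronic annotations).
DEFAULT_EXCLUDED_EVIDENCE = frozenset({"IEA"})

_GAF_MIN_FIELDS = 15


@dataclass(frozen=True)
class AnnotationRecord:
    """One protein-term association from a GAF file."""

    protein_id: str
    term_id: str
    evidence_code: str
    qualifier: str = ""

    def __post_init__(self):
        if not _EVIDENCE_RE.match(self.evidence_code):
            raise ValidationError(
                f"malformed evidence code {self.evidence_code!r} "
                f"for {self.protein_id}/{self.term_id}"
            )


@dataclass
class AnnotationMatrix:
    """Binary protein x GO-term matrix; rows proteins, columns terms."""

    proteins: list[str]
    terms: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.proteins), len(self.terms)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.proteins)} proteins x {len(self.terms)} terms"
            )
        if len(set(self.proteins)) != len(self.proteins):
            raise ValidationError("duplicate protein identifiers")
        if len(set(self.terms)) != len(self.terms):
            raise ValidationError("duplicate term identifiers")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "AnnotationMatrix":
        return AnnotationMatrix(list(self.proteins), list(self.terms), values)

    def select_columns(self, indices) -> "AnnotationMatrix":
        return AnnotationMatrix(
            list(self.proteins),
            [self.terms[j] for j in indices],
            self.values[:, list(indices)],
        )

    def select_rows(self, indices) -> "AnnotationMatrix":
        return AnnotationMatrix(
            [self.proteins[i] for i in indices],
            list(self.terms),
            self.values[list(indices), :],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.proteins, columns=self.terms)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationMatrix):
            return NotImplemented
        return (
            self.proteins == other.proteins
            and self.terms == other.terms
            and np.array_equal(self.values, other.values)
        )


@dataclass
class TemporalSplit:
    """Training matrix plus evaluation pairs from a newer snapshot.

    ``eval_positives`` are (protein, term) pairs that are 0 in the training
    matrix but annotated in the newer snapshot; ``eval_negatives`` are the
    remaining 0-pairs.  Together they partition the training matrix's zeros.
    """

    train: AnnotationMatrix
    eval_positives: set = field(default_factory=set)
    eval_negatives: set = field(default_factory=set)

    def __post_init__(self):
        if self.eval_positives & self.eval_negatives:
            raise ValidationError("evaluation positives and negatives overlap")

    def truth_and_mask(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense evaluation truth and mask aligned with the training matrix.

        Returns a binary truth matrix that is 1 on evaluation positives and
        a boolean mask that is True on exactly the zero-entries of the
        training matrix (the candidate pairs being scored).
        """
        prot = {p: i for i, p in enumerate(self.train.proteins)}
        term = {t: j for j, t in enumerate(self.train.terms)}
        truth = np.zeros(self.train.shape, dtype=np.int8)
        for p, t in self.eval_positives:
            truth[prot[p], term[t]] = 1
        mask = self.train.values == 0
        return truth, mask


def parse_gaf(path) -> list[AnnotationRecord]:
    """Parse a GAF 2.x file into annotation records.

    Reads the DB object ID (column 2), qualifier (4), GO ID (5) and evidence
    code (7).  Records whose qualifier contains ``NOT`` are dropped.
    Gzip-compressed input is accepted.

    Raises
    ------
    ParseError
        If a data line has fewer than 15 tab-separated fields.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    records: list[AnnotationRecord] = []
    with opener(path, "rt") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < _GAF_MIN_FIELDS:
                raise ParseError(
                    f"{path}: line {lineno}: expected at least "
                    f"{_GAF_MIN_FIELDS} tab-separated fields, got {len(fields)}"
                )
            qualifier = fields[3]
            if "NOT" in qualifier.split("|"):
                continue
            records.append(
                AnnotationRecord(
                    protein_id=fields[1],
                    term_id=fields[4],
                    evidence_code=fields[6],
                    qualifier=qualifier,
                )
            )
    return records


def filter_evidence(
    records: list[AnnotationRecord],
    excluded: frozenset[str] | set[str] = DEFAULT_EXCLUDED_EVIDENCE,
) -> list[AnnotationRecord]:
    """Drop records whose evidence code is in *excluded* (default: IEA)."""
    return [r for r in records if r.evidence_code not in excluded]


def _resolve_namespace(namespace: str) -> str:
    return NAMESPACE_ALIASES.get(namespace, namespace)


def build_matrix(
    records: list[AnnotationRecord],
    dag: GODag,
    namespace: str,
) -> AnnotationMatrix:
    """Build the true-path-closed, filtered annotation matrix.

    Keeps records whose term is an active term of *dag* in the requested
    namespace (``BP``/``CC``/``MF`` aliases accepted), closes the matrix
    under ancestors, removes root and unannotated columns, and drops
    proteins left with no annotation.

    Records referencing unknown or obsolete accessions are skipped with a
    warning — annotation snapshots routinely lag the ontology release.
    """
    namespace = _resolve_namespace(namespace)
    pairs: set[tuple[str, str]] = set()
    skipped = 0
    for rec in records:
        if rec.term_id not in dag:
            skipped += 1
            continue
        if dag.namespace_of(rec.term_id) != namespace:
            continue
        pairs.add((rec.protein_id, rec.term_id))
    if skipped:
        logger.warning(
            "skipped %d records with unknown or obsolete GO accessions", skipped
        )
    if not pairs:
        raise ValidationError(
            f"no annotation records survive for namespace {namespace!r}"
        )

    proteins = sorted({p for p, _ in pairs})
    terms = sorted({t for _, t in pairs})
    # Ancestor columns must exist before propagation can fill them.
    anc = set()
    for t in terms:
        anc |= dag.ancestors(t)
    terms = sorted(set(terms) | anc)

    prot_ix = {p: i for i, p in enumerate(proteins)}
    term_ix = {t: j for j, t in enumerate(terms)}
    values = np.zeros((len(proteins), len(terms)), dtype=np.int8)
    for p, t in pairs:
        values[prot_ix[p], term_ix[t]] = 1

    matrix = AnnotationMatrix(proteins, terms, values)
    matrix = propagate_true_path(matrix, dag)
    matrix = filter_terms(matrix, dag)
    keep_rows = [i for i in range(matrix.shape[0]) if matrix.values[i].any()]
    return matrix.select_rows(keep_rows)


def temporal_split(
    train_records: list[AnnotationRecord],
    validation_records: list[AnnotationRecord],
    dag: GODag,
    namespace: str,
) -> TemporalSplit:
    """Pair an older and a newer annotation snapshot for evaluation.

    Both matrices are built on the training snapshot's protein/term
    universe; proteins or terms that appear only in the newer snapshot are
    ignored, since a model trained on the older snapshot cannot score them.
    """
    if not train_records or not validation_records:
        raise ValidationError("both record lists must be non-empty")
    namespace = _resolve_namespace(namespace)
    train = build_matrix(train_records, dag, namespace)

    prot_ix = {p: i for i, p in enumerate(train.proteins)}
    term_set = set(train.terms)
    # Validation annotations, closed under ancestors, restricted to the
    # training universe.
    valid_pairs: set[tuple[str, str]] = set()
    for rec in validation_records:
        if rec.protein_id not in prot_ix or rec.term_id not in dag:
            continue
        if dag.namespace_of(rec.term_id) != namespace:
            continue
        closure = {rec.term_id} | dag.ancestors(rec.term_id)
        for t in closure & term_set:
            valid_pairs.add((rec.protein_id, t))

    term_ix = {t: j for j, t in enumerate(train.terms)}
    eval_positives = {
        (p, t) for p, t in valid_pairs if train.values[prot_ix[p], term_ix[t]] == 0
    }
    if not eval_positives:
        raise ValidationError(
            "nothing to evaluate: the newer snapshot adds no annotations "
            "within the training universe"
        )
    zero_rows, zero_cols = np.nonzero(train.values == 0)
    eval_negatives = {
        (train.proteins[i], train.terms[j])
        for i, j in zip(zero_rows.tolist(), zero_cols.tolist())
    } - eval_positives
    return TemporalSplit(train, eval_positives, eval_negatives)
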