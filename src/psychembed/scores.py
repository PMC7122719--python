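"""Low-dimensional patient scores derived from survey embedding matrices.

Three families of scores summarize the patient x d survey matrices:

* per-survey principal-component scores (``<survey>_PC1``, ``<survey>_PC2``),
* the first canonical correlation variable of the leading survey PCs against
  a 13-column self-rated symptom matrix (``<survey>_CCV1``),
* RDoC domain scores: cosine similarity between a seed-word-derived domain
  reference vector and a patient's response-weighted domain-specific vector
  (``RDoC_<domain>``).

Sign conventions are fixed deterministically (largest-|loading| coordinate
made positive) so bootstrap replicates are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import EmbeddingTable, IdfTable
from .embedder import Questionnaire, ResponseMatrix, SurveyMatrix, SurveyVectorizer

logger = logging.getLogger(__name__)

__all__ = [
    "DsmMatrix",
    "DomainSeeds",
    "pca_scores",
    "FirstCanonicalCorrelation",
    "cca_first_variable",
    "rdoc_domain_vector",
    "rdoc_patient_vector",
    "rdoc_score",
    "RdocScorer",
    "build_score_table",
    "read_domain_seeds",
    "write_domain_seeds",
]

# The five original RDoC domains; seed lists ship as editable defaults.
DEFAULT_RDOC_DOMAINS = (
    "negative_valence",
    "positive_valence",
    "cognitive_systems",
    "social_processes",
    "arousal_regulatory",
)


@dataclass
class DsmMatrix:
    """Patient x 13 self-rated symptom-domain severities."""

    patient_ids: list[str]
    values: np.ndarray

    N_DOMAINS = 13

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != self.N_DOMAINS:
            raise ValueError(
                f"DSM matrix must have exactly {self.N_DOMAINS} columns, "
                f"got shape {self.values.shape}"
            )
        if self.values.shape[0] != len(self.patient_ids):
            raise ValueError("row count does not match patient roster")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in DSM matrix")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DsmMatrix":
        return cls([str(i) for i in df.index], df.to_numpy(dtype=np.float64))


DomainSeeds = dict  # domain name -> list of seed tokens


def _fix_sign(loading: np.ndarray) -> float:
    """Sign that makes the largest-|value| coordinate of a loading positive."""
    k = int(np.argmax(np.abs(loading)))
    return 1.0 if loading[k] >= 0 else -1.0


def pca_scores(
    matrix: SurveyMatrix | np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores of a (column-centered) survey matrix.

    Returns ``(scores, explained_variance_ratio)`` where scores are the
    projections onto the leading right singular directions of the centered
    matrix.  Signs follow the largest-|loading|-positive convention.

    Raises on a zero-variance (constant) matrix.
    """
    X = matrix.matrix if isinstance(matrix, SurveyMatrix) else np.asarray(matrix)
    X = np.asarray(X, dtype=np.float64)
    n, d = X.shape
    if n_components > min(n, d):
        raise ValueError(f"n_components={n_components} exceeds min{(n, d)}")
    Xc = X - X.mean(axis=0)
    if not np.any(np.abs(Xc) > 1e-12):
        raise ValueError("zero variance: matrix is constant")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s**2))
    evr = (s[:n_components] ** 2) / total_var
    scores = U[:, :n_components] * s[:n_components]
    for k in range(n_components):
        sign = _fix_sign(Vt[k])
        scores[:, k] *= sign
    return scores, evr


class FirstCanonicalCorrelation(BaseEstimator, TransformerMixin):
    """First canonical correlation variable between two variable blocks.

    Classical CCA on z-scored blocks via the SVD of the whitened
    cross-covariance, with a small ridge (``reg``) added to each block
    covariance for rank safety.  ``transform`` projects the X block onto
    the first canonical direction; the canonical correlation is stored as
    ``rho_``.

    Fitted attributes: ``x_weights_``, ``y_weights_``, ``rho_``,
    ``x_mean_``, ``x_std_``, ``y_mean_``, ``y_std_``.
    """

    def __init__(self, reg: float = 1e-9):
        self.reg = reg

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "FirstCanonicalCorrelation":
        X = np.asarray(X, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if Y.ndim == 1:
            Y = Y[:, None]
        n = X.shape[0]
        if Y.shape[0] != n:
            raise ValueError("blocks have different numbers of rows")
        if X.shape[1] >= n or Y.shape[1] >= n:
            raise ValueError(
                f"too many columns for n={n} observations; "
                "reduce the number of components per block"
            )
        self.x_mean_, self.x_std_ = X.mean(0), X.std(0, ddof=1)
        self.y_mean_, self.y_std_ = Y.mean(0), Y.std(0, ddof=1)
        xs = np.where(self.x_std_ > 0, self.x_std_, 1.0)
        ys = np.where(self.y_std_ > 0, self.y_std_, 1.0)
        Xz = (X - self.x_mean_) / xs
        Yz = (Y - self.y_mean_) / ys

        Sxx = (Xz.T @ Xz) / (n - 1) + self.reg * np.eye(X.shape[1])
        Syy = (Yz.T @ Yz) / (n - 1) + self.reg * np.eye(Y.shape[1])
        Sxy = (Xz.T @ Yz) / (n - 1)
        Kx = np.linalg.inv(scipy.linalg.sqrtm(Sxx).real)
        Ky = np.linalg.inv(scipy.linalg.sqrtm(Syy).real)
        U, s, Vt = np.linalg.svd(Kx @ Sxy @ Ky)
        a = Kx @ U[:, 0]
        b = Ky @ Vt[0]
        sign = _fix_sign(a)
        self.x_weights_ = a * sign
        self.y_weights_ = b * sign
        self.rho_ = float(np.clip(s[0], 0.0, 1.0))
        self._xs = xs
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        Xz = (X - self.x_mean_) / self._xs
        return Xz @ self.x_weights_


def cca_first_variable(
    pcs: np.ndarray, dsm: DsmMatrix | np.ndarray, reg: float = 1e-9
) -> tuple[np.ndarray, float]:
    """First canonical variable of the PC block against the DSM block.

    Returns ``(ccv, rho1)`` — the per-patient projection of ``pcs`` onto the
    first canonical direction, and the first canonical correlation.
    """
    Y = dsm.values if isinstance(dsm, DsmMatrix) else np.asarray(dsm)
    model = FirstCanonicalCorrelation(reg=reg).fit(pcs, Y)
    return model.transform(pcs), model.rho_


# ---------------------------------------------------------------------------
# RDoC scores


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity with the zero-vector convention cos(0, .) = 0."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def rdoc_domain_vector(
    seeds: Sequence[str], emb: EmbeddingTable, idf: IdfTable, domain: str = "?"
) -> np.ndarray:
    """IDF-weighted average of the seed-word vectors of one domain.

    Seeds missing from the embedding or IDF vocabulary are skipped; if all
    seeds are out of vocabulary an error names the domain.
    """
    num = np.zeros(emb.dimension)
    den = 0.0
    for tok in seeds:
        v = emb.get(tok)
        w = idf.get(tok)
        if v is None or w is None:
            continue
        num += w * v
        den += w
    if den == 0.0:
        raise ValueError(f"domain {domain!r}: all seed words out of vocabulary")
    return num / den


def rdoc_patient_vector(
    answers: np.ndarray, question_vectors: np.ndarray, domain_vec: np.ndarray
) -> np.ndarray:
    """Domain-specific patient vector over the pooled question set.

    Weighted average of question vectors with weights
    ``w_j = a_j * cos(q_j, domain_vec)``; since cosines can be negative the
    normalizer is ``sum_j |w_j|``.  All-zero weights yield the zero vector
    with a logged warning.
    """
    answers = np.asarray(answers, dtype=np.float64)
    cos = np.array([_cosine(q, domain_vec) for q in question_vectors])
    w = answers * cos
    den = np.sum(np.abs(w))
    if den == 0.0:
        logger.warning("rdoc_patient_vector: all weights zero; zero vector")
        return np.zeros(question_vectors.shape[1])
    return (w @ question_vectors) / den


def rdoc_score(patient_vec: np.ndarray, domain_vec: np.ndarray) -> float:
    """Cosine similarity in [-1, 1] between patient and domain vectors."""
    return _cosine(patient_vec, domain_vec)


class RdocScorer(BaseEstimator, TransformerMixin):
    """Per-domain RDoC scores from pooled questionnaire responses.

    ``fit`` embeds every question of every survey (pooled across surveys)
    and every domain's seed list; ``transform`` maps a patient x question
    answer matrix (columns ordered as ``question_ids_``) to a
    patient x domain score matrix.

    Fitted attributes: ``question_vectors_`` (n_questions x d),
    ``question_ids_`` (``"survey/question"`` keys), ``domain_vectors_``
    (mapping), ``domains_``.
    """

    def __init__(
        self,
        embeddings: EmbeddingTable,
        idf: IdfTable,
        seeds: Mapping[str, Sequence[str]],
        missing: str = "median",
    ):
        self.embeddings = embeddings
        self.idf = idf
        self.seeds = seeds
        self.missing = missing

    def fit(self, questionnaires: Sequence[Questionnaire], y=None) -> "RdocScorer":
        if not self.seeds:
            raise ValueError("no RDoC domains given")
        self._vectorizers = {
            qn.survey_id: SurveyVectorizer(
                self.embeddings, self.idf, qn, missing=self.missing
            ).fit()
            for qn in questionnaires
        }
        self.question_ids_ = [
            f"{qn.survey_id}/{qid}"
            for qn in questionnaires
            for qid in qn.question_ids
        ]
        self.question_vectors_ = np.vstack(
            [self._vectorizers[qn.survey_id].question_vectors_ for qn in questionnaires]
        )
        self._questionnaires = list(questionnaires)
        self.domains_ = list(self.seeds)
        self.domain_vectors_ = {
            dom: rdoc_domain_vector(toks, self.embeddings, self.idf, domain=dom)
            for dom, toks in self.seeds.items()
        }
        return self

    def transform(
        self, responses: Mapping[str, ResponseMatrix | pd.DataFrame]
    ) -> pd.DataFrame:
        """Score each patient on each domain; returns a DataFrame."""
        blocks = []
        roster = None
        for qn in self._questionnaires:
            resp = responses[qn.survey_id]
            if isinstance(resp, pd.DataFrame):
                resp = ResponseMatrix.from_frame(resp)
            if roster is None:
                roster = list(resp.patient_ids)
            elif list(resp.patient_ids) != roster:
                raise ValueError(
                    f"survey {qn.survey_id!r}: patient order differs from "
                    f"survey {self._questionnaires[0].survey_id!r}"
                )
            vec = self._vectorizers[qn.survey_id]
            order = [resp.question_ids.index(q) for q in vec.question_ids_]
            ans = resp.answers[:, order]
            blocks.append(vec._impute(ans, roster))
        answers = np.hstack(blocks)

        out = np.zeros((len(roster), len(self.domains_)))
        for k, dom in enumerate(self.domains_):
            dvec = self.domain_vectors_[dom]
            for i in range(len(roster)):
                pvec = rdoc_patient_vector(answers[i], self.question_vectors_, dvec)
                out[i, k] = rdoc_score(pvec, dvec)
        return pd.DataFrame(
            out,
            index=pd.Index(roster, name="patient_id"),
            columns=[f"RDoC_{d}" for d in self.domains_],
        )


def build_score_table(
    surveys: Mapping[str, SurveyMatrix],
    dsm: DsmMatrix | None = None,
    n_pcs: int = 2,
    cca_variance_target: float = 0.8,
    cca_max_pcs: int = 10,
    rdoc: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the patient score table from per-survey matrices.

    Columns: ``<survey>_PC1..PCk`` for every survey, ``<survey>_CCV1`` if a
    DSM matrix is supplied, and any precomputed RDoC columns.  The number of
    PCs fed to CCA is the smallest count explaining ``cca_variance_target``
    of variance, capped at ``cca_max_pcs``.
    """
    first = next(iter(surveys.values()))
    roster = list(first.patient_ids)
    cols: dict[str, np.ndarray] = {}
    for sid in sorted(surveys):
        sm = surveys[sid]
        if list(sm.patient_ids) != roster:
            raise ValueError(f"survey {sid!r}: roster differs")
        k_max = min(cca_max_pcs, min(sm.matrix.shape) - 1)
        scores, evr = pca_scores(sm, max(n_pcs, k_max))
        for k in range(n_pcs):
            cols[f"{sid}_PC{k + 1}"] = scores[:, k]
        if dsm is not None:
            if list(dsm.patient_ids) != roster:
                raise ValueError("DSM matrix roster differs from surveys")
            k_cca = int(np.searchsorted(np.cumsum(evr), cca_variance_target) + 1)
            k_cca = min(max(k_cca, 1), k_max)
            ccv, rho = cca_first_variable(scores[:, :k_cca], dsm)
            cols[f"{sid}_CCV1"] = ccv
    df = pd.DataFrame(cols, index=pd.Index(roster, name="patient_id"))
    if rdoc is not None:
        df = df.join(rdoc)
    return df


# ---------------------------------------------------------------------------
# seed-file format: "domain<TAB>seed1 seed2 ..."


def read_domain_seeds(path: str | Path) -> dict[str, list[str]]:
    seeds: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        if "\t" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'domain<TAB>seeds...'")
        dom, toks = line.split("\t", 1)
        if dom in seeds:
            raise ValueError(f"{path}:{lineno}: duplicate domain {dom!r}")
        words = toks.split()
        if not words:
            raise ValueError(f"{path}:{lineno}: no seeds for domain {dom!r}")
        seeds[dom] = words
    if not seeds:
        raise ValueError(f"{path}: no domains found")
    return seeds


def default_domain_seeds() -> dict[str, list[str]]:
    """Editable placeholder seed lists for the five original RDoC domains.

    The shipped seeds are generic English words per domain; substitute a
    published domain seed-word list matched to your embedding vocabulary
    for real analyses.
    """
    path = Path(__file__).parent / "data" / "rdoc_seeds_default.tsv"
    return read_domain_seeds(path)


def write_domain_seeds(seeds: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for dom, toks in seeds.items():
            fh.write(f"{dom}\t{' '.join(toks)}\n")
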