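"""Synthetic cohort generator.

The clinical cohort behind this method (310 outpatients and healthy
participants answering nine ordinal symptom surveys) was never deposited,
so every stage of the pipeline is exercised on synthetic data that
reproduces the statistical structure the method assumes:

* a semantic embedding space whose tokens cluster into latent symptom
  domains (topics), with log-uniform IDF weights and per-domain seed words;
* a three-group cohort (case / control / supercontrol) whose ordinal
  answers are driven by latent per-domain severities through a
  graded-threshold (cumulative-probit-style) response model;
* a 13-column self-rated symptom matrix and neurocognitive-style outcome
  measures, both linear in the latent severities plus noise.

The ground truth (latent severities, question-to-domain assignment, group
labels) is returned alongside the data so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .corpus import EmbeddingTable, IdfTable, write_embeddings, write_idf
from .embedder import (
    Question,
    Questionnaire,
    ResponseMatrix,
    write_questionnaires,
)
from .scores import DsmMatrix, write_domain_seeds

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimSpace",
    "make_embedding_space",
    "make_cohort",
    "make_outcomes",
    "simulate_study",
    "write_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition settings for the synthetic cohort.

    Defaults emulate the motivating study: 310 patients in three a-priori
    groups (the case fraction matches the cohort's 198/310; the split of
    the remainder into controls and supercontrols is the package's choice),
    nine ordinal surveys over five latent symptom domains, and a mean
    latent severity shift of 2 SD for cases (1 SD for controls).  Embedding
    dimension and vocabulary are scaled to desk size (d=50, vocabulary 500);
    full scale (d=500) is reachable by configuration.
    """

    n_patients: int = 310
    prop_case: float = 0.64
    prop_control: float = 0.13
    prop_supercontrol: float = 0.23
    n_domains: int = 5
    n_surveys: int = 9
    questions_per_survey: int = 10
    vocab_size: int = 500
    embed_dim: int = 50
    effect_size: float = 2.0  # latent mean shift for cases, in SD units
    ordinal_levels: int = 5
    noise_sd: float = 1.0  # response noise on the latent scale
    tokens_per_question: int = 6
    seeds_per_domain: int = 8
    n_dsm_columns: int = 13
    outcome_beta: float = 1.0
    outcome_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        props = (self.prop_case, self.prop_control, self.prop_supercontrol)
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"group proportions must sum to 1, got {props}")
        for name in (
            "n_patients",
            "n_domains",
            "n_surveys",
            "questions_per_survey",
            "vocab_size",
            "embed_dim",
            "ordinal_levels",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.vocab_size < self.n_domains * 10:
            raise ValueError("vocab_size must be at least 10 tokens per domain")

    @property
    def domains(self) -> list[str]:
        return [f"dom{k + 1}" for k in range(self.n_domains)]


@dataclass
class SimTruth:
    """Ground truth stored alongside synthetic outputs for recovery tests."""

    z: np.ndarray  # patient x domain latent severities
    question_domain: dict[str, int]  # "survey/question" -> domain index
    groups: list[str]  # per patient, aligned with patient_ids
    patient_ids: list[str]
    domains: list[str]


@dataclass
class SimSpace:
    """Synthetic embedding space: embeddings, IDF, topic structure, seeds."""

    embeddings: EmbeddingTable
    idf: IdfTable
    seeds: dict[str, list[str]]
    token_domain: dict[str, int]
    centroids: np.ndarray


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def make_embedding_space(cfg: SimConfig) -> SimSpace:
    """Topic-structured embedding space with IDF weights and seed words.

    Tokens are partitioned round-robin into ``n_domains`` topics; each token
    vector is its topic centroid (centroids are mutually orthogonal unit
    vectors, scaled) plus isotropic Gaussian noise, so within-topic cosines
    exceed between-topic cosines.  IDF weights are drawn log-uniformly on
    [0.5, 5].  Each domain's seed words are its tokens nearest the centroid.
    """
    rng = _rngs(cfg.seed, 3)[0]
    D, V, K = cfg.embed_dim, cfg.vocab_size, cfg.n_domains
    if K > D:
        raise ValueError("need embed_dim >= n_domains for orthogonal topics")
    Q, _ = np.linalg.qr(rng.standard_normal((D, K)))
    centroids = Q.T  # K orthonormal rows

    tokens = [f"t{i:04d}" for i in range(V)]
    token_domain = {tok: i % K for i, tok in enumerate(tokens)}
    noise = 0.35
    entries = {}
    for tok in tokens:
        entries[tok] = centroids[token_domain[tok]] + noise * rng.standard_normal(D) / np.sqrt(D)
    emb = EmbeddingTable(dimension=D, entries=entries)

    idf_w = np.exp(rng.uniform(np.log(0.5), np.log(5.0), size=V))
    idf = IdfTable(n_documents=V, weights=dict(zip(tokens, idf_w)))

    seeds: dict[str, list[str]] = {}
    for k, dom in enumerate(cfg.domains):
        members = [t for t in tokens if token_domain[t] == k]
        cos = [
            float(entries[t] @ centroids[k] / np.linalg.norm(entries[t]))
            for t in members
        ]
        order = np.argsort(cos)[::-1][: cfg.seeds_per_domain]
        seeds[dom] = [members[i] for i in order]
    return SimSpace(
        embeddings=emb,
        idf=idf,
        seeds=seeds,
        token_domain=token_domain,
        centroids=centroids,
    )


def make_cohort(
    cfg: SimConfig, space: SimSpace
) -> tuple[list[Questionnaire], dict[str, ResponseMatrix], DsmMatrix, dict[str, str], SimTruth]:
    """Synthetic cohort: questionnaires, ordinal responses, DSM matrix, labels.

    Latent severities are ``z_i ~ N(mu_group, I)`` per domain with
    ``mu = effect_size`` for cases, ``effect_size / 2`` for controls and 0
    for supercontrols.  Each question belongs to one domain (cycling within
    each survey) and its text is sampled from that domain's topic tokens.
    Ordinal answers follow a graded-threshold model: the latent
    ``z_i[domain(j)] + noise`` is cut into ``ordinal_levels`` bins by fixed
    thresholds centered between the group means.  The 13-column DSM-style
    matrix is a linear map of ``z`` plus noise, each column loading chiefly
    on one domain (cycling).
    """
    rng = _rngs(cfg.seed, 3)[1]
    n, K, L = cfg.n_patients, cfg.n_domains, cfg.ordinal_levels
    delta = cfg.effect_size

    n_case = int(round(cfg.prop_case * n))
    n_control = int(round(cfg.prop_control * n))
    n_super = n - n_case - n_control
    groups = ["case"] * n_case + ["control"] * n_control + ["supercontrol"] * n_super
    patient_ids = [f"p{i:04d}" for i in range(n)]
    mu = {"case": delta, "control": delta / 2.0, "supercontrol": 0.0}
    z = np.vstack([mu[g] + rng.standard_normal(K) for g in groups])

    s = np.sqrt(1.0 + cfg.noise_sd**2)
    center = delta / 2.0
    thresholds = center + s * norm.ppf(np.arange(1, L) / L)

    questionnaires: list[Questionnaire] = []
    responses: dict[str, ResponseMatrix] = {}
    question_domain: dict[str, int] = {}
    domain_tokens = {
        k: [t for t, d in space.token_domain.items() if d == k] for k in range(K)
    }
    for s_idx in range(cfg.n_surveys):
        sid = f"survey{s_idx + 1:02d}"
        qs = []
        answers = np.empty((n, cfg.questions_per_survey))
        for j in range(cfg.questions_per_survey):
            dom = (s_idx + j) % K
            qid = f"q{j + 1:02d}"
            words = rng.choice(
                domain_tokens[dom], size=cfg.tokens_per_question, replace=False
            )
            qs.append(
                Question(
                    survey_id=sid,
                    question_id=qid,
                    text=" ".join(words),
                    scale_min=0,
                    scale_max=L - 1,
                )
            )
            question_domain[f"{sid}/{qid}"] = dom
            u = z[:, dom] + cfg.noise_sd * rng.standard_normal(n)
            answers[:, j] = np.searchsorted(thresholds, u)
        questionnaires.append(Questionnaire(survey_id=sid, questions=tuple(qs)))
        responses[sid] = ResponseMatrix(
            patient_ids=list(patient_ids),
            question_ids=[q.question_id for q in qs],
            answers=answers,
        )

    loadings = np.zeros((cfg.n_dsm_columns, K))
    for c in range(cfg.n_dsm_columns):
        loadings[c, c % K] = 1.0
        loadings[c] += 0.2 * rng.standard_normal(K)
    dsm_vals = z @ loadings.T + 0.5 * rng.standard_normal((n, cfg.n_dsm_columns))
    dsm = DsmMatrix(patient_ids=list(patient_ids), values=dsm_vals)

    labels = dict(zip(patient_ids, groups))
    truth = SimTruth(
        z=z,
        question_domain=question_domain,
        groups=groups,
        patient_ids=list(patient_ids),
        domains=cfg.domains,
    )
    return questionnaires, responses, dsm, labels, truth


def make_outcomes(cfg: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Outcome table: one noisy linear readout of each latent domain.

    ``outcome_<dom> = beta * z[:, dom] + noise``; a pure-noise column
    ``noise_ctrl`` is always included as a negative control.
    """
    rng = _rngs(cfg.seed, 3)[2]
    n = truth.z.shape[0]
    cols = {}
    for k, dom in enumerate(truth.domains):
        cols[f"outcome_{dom}"] = (
            cfg.outcome_beta * truth.z[:, k]
            + cfg.outcome_noise_sd * rng.standard_normal(n)
        )
    cols["noise_ctrl"] = rng.standard_normal(n)
    return pd.DataFrame(cols, index=pd.Index(truth.patient_ids, name="patient_id"))


def simulate_study(cfg: SimConfig) -> dict:
    """Generate the full synthetic study in one call.

    Returns a dict with keys ``space``, ``questionnaires``, ``responses``,
    ``dsm``, ``labels``, ``truth``, ``outcomes``.
    """
    space = make_embedding_space(cfg)
    questionnaires, responses, dsm, labels, truth = make_cohort(cfg, space)
    outcomes = make_outcomes(cfg, truth)
    return {
        "space": space,
        "questionnaires": questionnaires,
        "responses": responses,
        "dsm": dsm,
        "labels": labels,
        "truth": truth,
        "outcomes": outcomes,
    }


def write_dataset(study: dict, out_dir: str | Path) -> None:
    """Write all synthetic artifacts in the formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    space: SimSpace = study["space"]
    write_embeddings(space.embeddings, out / "embeddings.txt")
    write_idf(space.idf, out / "idf.tsv")
    write_domain_seeds(space.seeds, out / "rdoc_seeds.tsv")
    write_questionnaires(study["questionnaires"], out / "questionnaires.tsv")
    for sid, resp in study["responses"].items():
        df = resp.to_frame()
        df.index.name = "patient_id"
        df.to_csv(out / f"responses_{sid}.csv")
    dsm: DsmMatrix = study["dsm"]
    pd.DataFrame(
        dsm.values,
        index=pd.Index(dsm.patient_ids, name="patient_id"),
        columns=[f"dsm{c + 1:02d}" for c in range(dsm.values.shape[1])],
    ).to_csv(out / "dsm.csv")
    pd.Series(study["labels"], name="group").rename_axis("patient_id").to_csv(
        out / "labels.csv"
    )
    study["outcomes"].to_csv(out / "outcomes.csv")
    truth: SimTruth = study["truth"]
    pd.DataFrame(
        truth.z,
        index=pd.Index(truth.patient_ids, name="patient_id"),
        columns=[f"z_{d}" for d in truth.domains],
    ).to_csv(out / "truth_z.csv")
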