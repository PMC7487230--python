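"""Synthetic corpora with planted concept structure and exact ground truth.

Articles receive latent binary concept memberships drawn from a pairwise
dependence model: each concept has a base prevalence p_a, and selected pairs
have their joint probability targeted at ``boost_ab * p_a * p_b`` (1 =
independence, 0 = a planted gap, >1 = a planted connection). For up to 12
concepts the joint distribution over all 2^m membership patterns is fitted
exactly by iterative proportional fitting and sampled directly; above that a
Gibbs sampler over the corresponding log-linear model is used (approximate
moments; documented).

For every held concept, each of its keywords is planted independently with
probability q into a randomly chosen field (title / abstract / author
keywords / KeyWords Plus). Keyword tokens are pseudowords, pairwise distinct
across keywords, of fixed length, and disjoint from the distractor
vocabulary — so with q = 1 the tagger recovers the latent memberships
exactly and expected matrices are exact:

    E[N_ab] = n * P(a and b) * d_a(q) * d_b(q),   d_a(q) = 1 - (1 - q)^{K_a}
    E[C_ab] = E[N_ab] / (K_a + K_b)
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from litmap.corpus import ArticleRecord, Corpus
from litmap.errors import ConfigError
from litmap.scheme import PARENT, ConceptNode, ConceptScheme, KeywordAssignment

EXACT_ENUM_LIMIT = 12

_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aeiou"
_SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]


@dataclass
class ConceptSpec:
    """One synthetic concept: name, category, and how many keywords it owns."""

    name: str
    category: str
    n_keywords: int = 4


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic corpus generator.

    ``pair_boost`` maps unordered concept-name pairs to joint-probability
    multipliers; absent pairs default to 1 (independence).
    """

    n_articles: int
    concepts: list[ConceptSpec]
    base_prevalence: dict[str, float]
    pair_boost: dict[frozenset, float] = field(default_factory=dict)
    keyword_emission_prob: float = 1.0
    distractor_vocab_size: int = 200
    title_tokens: int = 6
    abstract_tokens: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        self.pair_boost = {frozenset(k): float(v) for k, v in self.pair_boost.items()}
        self.validate()

    def validate(self) -> None:
        problems: list[str] = []
        if self.n_articles <= 0:
            problems.append(f"n_articles must be positive, got {self.n_articles}")
        names = [c.name for c in self.concepts]
        if len(set(names)) != len(names):
            problems.append("concept names must be distinct")
        for c in self.concepts:
            if c.n_keywords <= 0:
                problems.append(f"concept {c.name!r}: n_keywords must be positive")
        for name in names:
            p = self.base_prevalence.get(name)
            if p is None:
                problems.append(f"concept {name!r}: missing base_prevalence")
            elif not 0.0 < p < 1.0:
                problems.append(f"concept {name!r}: prevalence {p} outside (0, 1)")
        for pair, boost in self.pair_boost.items():
            if len(pair) != 2 or not pair <= set(names):
                problems.append(f"pair_boost key {sorted(pair)} is not a pair of known concepts")
            elif boost < 0:
                problems.append(f"pair_boost[{sorted(pair)}] = {boost} is negative")
        if not 0.0 < self.keyword_emission_prob <= 1.0:
            problems.append(
                f"keyword_emission_prob {self.keyword_emission_prob} outside (0, 1]"
            )
        if self.distractor_vocab_size <= 0:
            problems.append("distractor_vocab_size must be positive")
        if self.title_tokens <= 0 or self.abstract_tokens < 0:
            problems.append("title/abstract token counts invalid")
        if problems:
            raise ConfigError("invalid SyntheticConfig:\n  " + "\n  ".join(problems))

    @property
    def concept_names(self) -> list[str]:
        return [c.name for c in self.concepts]

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        concepts = [
            ConceptSpec(
                name=c["name"],
                category=c.get("category", "General"),
                n_keywords=int(c.get("keywords", 4)),
            )
            for c in raw["concepts"]
        ]
        prevalence = raw.get("base_prevalence", 0.2)
        if isinstance(prevalence, (int, float)):
            prevalence = {c.name: float(prevalence) for c in concepts}
        boosts = {}
        for entry in raw.get("pair_boost", []):
            a, b, value = entry
            boosts[frozenset((a, b))] = float(value)
        return cls(
            n_articles=int(raw["n_articles"]),
            concepts=concepts,
            base_prevalence={k: float(v) for k, v in prevalence.items()},
            pair_boost=boosts,
            keyword_emission_prob=float(raw.get("keyword_emission_prob", 1.0)),
            distractor_vocab_size=int(raw.get("distractor_vocab_size", 200)),
            title_tokens=int(raw.get("title_tokens", 6)),
            abstract_tokens=int(raw.get("abstract_tokens", 40)),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class GroundTruth:
    """Latent memberships plus exact expected count/connectivity matrices."""

    node_names: list[str]
    true_tags: list[set[str]]
    expected_counts: np.ndarray
    expected_connectivity: np.ndarray


class PairwiseJointModel:
    """Joint distribution of binary concept memberships with pairwise targets.

    For m <= 12 concepts the 2^m state probabilities are fitted by iterative
    proportional fitting so that every marginal P(a) = p_a exactly and every
    boosted pair has P(a and b) = boost_ab * p_a * p_b exactly. Infeasible
    targets (outside the Frechet bounds, or IPF non-convergence) raise
    :class:`~litmap.errors.ConfigError` before any sampling.
    """

    def __init__(self, names: Sequence[str], p: Sequence[float], boosts: dict[frozenset, float]):
        self.names = list(names)
        self.m = len(self.names)
        self.p = np.asarray(p, dtype=float)
        self._index = {name: i for i, name in enumerate(self.names)}
        self.targets: dict[tuple[int, int], float] = {}
        for pair, boost in boosts.items():
            if boost == 1.0:
                continue
            a, b = sorted(self._index[name] for name in pair)
            self.targets[(a, b)] = boost * self.p[a] * self.p[b]
        self._check_feasible()
        self.exact = self.m <= EXACT_ENUM_LIMIT
        if self.exact:
            self._fit_exact()

    def _check_feasible(self) -> None:
        for (a, b), t in self.targets.items():
            lo = max(0.0, self.p[a] + self.p[b] - 1.0)
            hi = min(self.p[a], self.p[b])
            if not lo - 1e-12 <= t <= hi + 1e-12:
                raise ConfigError(
                    f"joint target P({self.names[a]} & {self.names[b]}) = {t:.6g} "
                    f"outside feasible range [{lo:.6g}, {hi:.6g}]"
                )

    # -- exact regime ---------------------------------------------------------

    def _fit_exact(self, tol: float = 1e-13, max_cycles: int = 20000) -> None:
        m = self.m
        states = ((np.arange(2**m)[:, None] >> np.arange(m)) & 1).astype(bool)
        self.states = states
        # independence start
        logp = states @ np.log(self.p) + (~states) @ np.log1p(-self.p)
        probs = np.exp(logp)
        probs /= probs.sum()

        single_masks = [states[:, a] for a in range(m)]
        pair_masks = {key: states[:, key[0]] & states[:, key[1]] for key in self.targets}

        for _ in range(max_cycles):
            worst = 0.0
            for a in range(m):
                cur = probs[single_masks[a]].sum()
                worst = max(worst, abs(cur - self.p[a]))
                probs = self._rescale(probs, single_masks[a], cur, self.p[a])
            for key, t in self.targets.items():
                cur = probs[pair_masks[key]].sum()
                worst = max(worst, abs(cur - t))
                probs = self._rescale(probs, pair_masks[key], cur, t)
            if worst < tol:
                break
        else:
            raise ConfigError(
                f"IPF failed to converge (last max deviation {worst:.3g}); "
                "the pairwise targets are jointly infeasible or nearly so"
            )
        self.probs = probs / probs.sum()

    @staticmethod
    def _rescale(probs: np.ndarray, mask: np.ndarray, current: float, target: float) -> np.ndarray:
        out = probs.copy()
        if current > 0:
            out[mask] *= target / current
        elif target > 0:
            raise ConfigError("pairwise targets are jointly infeasible (mass vanished)")
        rest = 1.0 - current
        if rest > 0:
            out[~mask] *= (1.0 - target) / rest
        return out

    # -- queries --------------------------------------------------------------

    def marginal(self, name: str) -> float:
        return float(self.p[self._index[name]])

    def pair_prob(self, a: str, b: str) -> float:
        """P(a and b); exact in the enumerable regime."""
        i, j = self._index[a], self._index[b]
        if i == j:
            return float(self.p[i])
        key = tuple(sorted((i, j)))
        if self.exact:
            return float(self.probs[self.states[:, key[0]] & self.states[:, key[1]]].sum())
        if key in self.targets:
            return self.targets[key]
        return float(self.p[i] * self.p[j])  # approximate above the enumeration limit

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n iid membership vectors, shape (n, m) boolean."""
        if self.exact:
            draws = rng.choice(len(self.probs), size=n, p=self.probs)
            return self.states[draws]
        return self._gibbs(n, rng)

    def _gibbs(self, n: int, rng: np.random.Generator, sweeps: int = 40) -> np.ndarray:
        """Gibbs sampling from the log-linear model with alpha = logit(p),
        beta = log(boost); moments match the targets only approximately."""
        m = self.m
        alpha = np.log(self.p) - np.log1p(-self.p)
        beta = np.zeros((m, m))
        hard_zero = np.zeros((m, m), dtype=bool)
        for (a, b), t in self.targets.items():
            boost = t / (self.p[a] * self.p[b])
            if boost == 0.0:
                hard_zero[a, b] = hard_zero[b, a] = True
            else:
                beta[a, b] = beta[b, a] = np.log(boost)
        z = rng.random((n, m)) < self.p
        for a, b in zip(*np.nonzero(np.triu(hard_zero))):
            both = z[:, a] & z[:, b]
            z[both, b] = False
        for _ in range(sweeps):
            for a in rng.permutation(m):
                eta = alpha[a] + z @ beta[a]
                blocked = z[:, hard_zero[a]].any(axis=1)
                prob = 1.0 / (1.0 + np.exp(-eta))
                prob[blocked] = 0.0
                z[:, a] = rng.random(n) < prob
        return z


def build_model(config: SyntheticConfig) -> PairwiseJointModel:
    return PairwiseJointModel(
        config.concept_names,
        [config.base_prevalence[name] for name in config.concept_names],
        config.pair_boost,
    )


# -- pseudoword vocabulary ----------------------------------------------------


def _make_tokens(count: int, rng: np.random.Generator, taken: set[str]) -> list[str]:
    """Distinct 3-syllable pseudowords (fixed length, so no token is a prefix
    of another — word-start matching cannot cross keyword/distractor lines)."""
    out: list[str] = []
    while len(out) < count:
        token = "".join(rng.choice(_SYLLABLES) for _ in range(3))
        if token not in taken:
            taken.add(token)
            out.append(token)
    return out


def generate_scheme(config: SyntheticConfig, rng_seed: Optional[int] = None) -> ConceptScheme:
    """Generate a parent-level concept scheme with planted pseudoword keywords.

    Each concept owns ``n_keywords`` phrases of 2-3 tokens; tokens are unique
    to their keyword, so keywords can never shadow one another. Deterministic
    given the seed.
    """
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    taken: set[str] = set()
    nodes = [ConceptNode(name=c.name, category=c.category, level=PARENT) for c in config.concepts]
    assignments: list[KeywordAssignment] = []
    for c in config.concepts:
        for _ in range(c.n_keywords):
            n_tokens = int(rng.integers(2, 4))
            phrase = " ".join(_make_tokens(n_tokens, rng, taken))
            assignments.append(KeywordAssignment(keyword=phrase, parent_name=c.name))
    return ConceptScheme(nodes, assignments)


def _distractor_vocab(config: SyntheticConfig, scheme: ConceptScheme) -> list[str]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD157]))
    taken = {tok for a in scheme.assignments for tok in a.keyword.split()}
    return _make_tokens(config.distractor_vocab_size, rng, taken)


# -- corpus generation --------------------------------------------------------

_FIELDS = ("title", "abstract", "de", "id")


def generate_corpus(
    scheme: ConceptScheme,
    config: SyntheticConfig,
    rng_seed: Optional[int] = None,
) -> tuple[Corpus, GroundTruth]:
    """Sample a corpus of articles with planted concept keywords.

    Memberships come from the pairwise joint model; each keyword of a held
    concept is planted with probability q into one random field. Distractor
    tokens fill the title and abstract to their configured lengths.
    """
    model = build_model(config)
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    keywords_of: dict[str, list[str]] = {name: [] for name in config.concept_names}
    for a in scheme.assignments:
        if a.parent_name in keywords_of:
            keywords_of[a.parent_name].append(a.keyword)
    for name, kws in keywords_of.items():
        if not kws:
            raise ConfigError(f"scheme has no keywords for concept {name!r}")

    vocab = _distractor_vocab(config, scheme)
    q = config.keyword_emission_prob
    z = model.sample(config.n_articles, rng)

    records: list[ArticleRecord] = []
    true_tags: list[set[str]] = []
    for i in range(config.n_articles):
        held = {name for j, name in enumerate(config.concept_names) if z[i, j]}
        true_tags.append(held)
        # title/abstract are lists of chunks (a distractor token or a whole
        # keyword phrase); phrases are inserted at chunk boundaries so a later
        # insertion can never split an earlier phrase
        title = [str(t) for t in rng.choice(vocab, size=config.title_tokens)]
        abstract = [str(t) for t in rng.choice(vocab, size=config.abstract_tokens)]
        de: list[str] = [str(rng.choice(vocab))]
        idk: list[str] = [str(rng.choice(vocab))]
        for name in sorted(held):
            for kw in keywords_of[name]:
                if q < 1.0 and rng.random() >= q:
                    continue
                target = _FIELDS[rng.integers(len(_FIELDS))]
                if target == "title":
                    title.insert(int(rng.integers(len(title) + 1)), kw)
                elif target == "abstract":
                    abstract.insert(int(rng.integers(len(abstract) + 1)), kw)
                elif target == "de":
                    de.append(kw)
                else:
                    idk.append(kw)
        records.append(
            ArticleRecord(
                record_id=f"SYN-{i:06d}",
                title=" ".join(title),
                abstract=" ".join(abstract),
                author_keywords=de,
                keywords_plus=idk,
                year=int(rng.integers(1990, 2026)),
            )
        )

    truth = GroundTruth(
        node_names=list(config.concept_names),
        true_tags=true_tags,
        expected_counts=_expected_counts(config, scheme, model),
        expected_connectivity=_expected_connectivity_matrix(config, scheme, model),
    )
    return Corpus(records=records, source_label="synthetic"), truth


def _detection(config: SyntheticConfig, scheme: ConceptScheme, name: str) -> float:
    q = config.keyword_emission_prob
    return 1.0 - (1.0 - q) ** scheme.keyword_count(name)


def _expected_counts(config, scheme, model) -> np.ndarray:
    names = config.concept_names
    n = config.n_articles
    m = len(names)
    out = np.zeros((m, m))
    for i, a in enumerate(names):
        d_a = _detection(config, scheme, a)
        out[i, i] = n * model.marginal(a) * d_a
        for j in range(i + 1, m):
            b = names[j]
            value = n * model.pair_prob(a, b) * d_a * _detection(config, scheme, b)
            out[i, j] = out[j, i] = value
    return out


def _expected_connectivity_matrix(config, scheme, model) -> np.ndarray:
    names = config.concept_names
    counts = _expected_counts(config, scheme, model)
    m = len(names)
    out = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        denom = scheme.keyword_count(names[i]) + scheme.keyword_count(names[j])
        out[i, j] = out[j, i] = counts[i, j] / denom
    return out


def expected_connectivity(config: SyntheticConfig, scheme: ConceptScheme) -> tuple[list[str], np.ndarray]:
    """Expected connectivity matrix E[C] under the configured joint model.

    E[C_ab] = n * P(a and b) * d_a(q) * d_b(q) / (K_a + K_b); exact in the
    enumerable regime (and exactly so for q = 1).
    """
    model = build_model(config)
    return list(config.concept_names), _expected_connectivity_matrix(config, scheme, model)
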