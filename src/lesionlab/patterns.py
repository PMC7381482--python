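"""Synthetic binary feature-pattern sets for the hub-and-spoke simulations.

Each pattern set contains 48 items over 216 binary units, organised as a
40-unit name block, a 64-unit visual block and a 112-unit verbal block.
Items fall into six categories of eight exemplars each -- birds, mammals
and fruits (the animate, "animal" domain) and tools, vehicles and household
objects (the artefact domain).  The two domains occupy disjoint visual and
verbal feature slots, so cross-domain correlations are near zero, while
domain-shared and category-specific feature blocks give the within-domain /
within-category correlational structure characteristic of feature-norm
derived semantic training sets.

Two calibrated templates are provided.  The "P1-like" profile reproduces the
per-category mean feature counts of the pattern set distributed with the
PDPTool release of the model; the "P2-like" profile reproduces the counts of
sets drawn from the original probabilistic template.  Activation
probabilities are scaled per category so that the closed-form expected
active-feature count (including the single active name unit) equals the
calibration target exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_NAME = 40
N_VISUAL = 64
N_VERBAL = 112
N_UNITS = N_NAME + N_VISUAL + N_VERBAL  # 216
N_FEATURES = N_VISUAL + N_VERBAL  # 176 stochastic feature slots
N_ITEMS = 48
ITEMS_PER_CATEGORY = 8

CATEGORIES = ("birds", "mammals", "fruits", "tools", "vehicles", "household")
DOMAIN_OF = {
    "birds": "animal",
    "mammals": "animal",
    "fruits": "animal",
    "tools": "artefact",
    "vehicles": "artefact",
    "household": "artefact",
}

# Per-category mean active-feature counts (over all 216 units) of the two
# reference pattern sets.
P1_MEANS = {
    "birds": 42.250,
    "mammals": 41.375,
    "fruits": 47.625,
    "tools": 25.375,
    "vehicles": 27.500,
    "household": 22.500,
}
P2_MEANS = {
    "birds": 35.875,
    "mammals": 36.750,
    "fruits": 31.500,
    "tools": 24.250,
    "vehicles": 28.625,
    "household": 24.625,
}


class UnknownProfileError(ValueError):
    """Raised when an unrecognised profile id is requested."""


class PatternFormatError(ValueError):
    """Raised when a pattern file fails validation."""


# ---------------------------------------------------------------------------
# Feature-slot layout
#
# A 24-slot global block (visual 0..11, verbal 0..11) carries high-probability
# features shared by every item (concrete-object generalities); it keeps
# cross-domain correlations near zero rather than strongly negative.  The
# remaining slots split by domain: visual 12..37 / verbal 12..61 are animal,
# visual 38..63 / verbal 62..111 artefact.  Within each domain, 16 slots are
# domain-shared and each category owns a block of 7 visual + 12 verbal slots.
# ---------------------------------------------------------------------------

_GLOBAL_SLOTS = np.concatenate([np.arange(0, 12), N_VISUAL + np.arange(0, 12)])


def _domain_slots(domain: str) -> dict[str, np.ndarray]:
    """Index arrays (into the 176 feature slots) for one domain's blocks."""
    if domain == "animal":
        vis0, verb0 = 12, 12
    else:
        vis0, verb0 = 38, 62
    vis = np.arange(vis0, vis0 + 26)
    verb = N_VISUAL + np.arange(verb0, verb0 + 50)
    blocks = {"shared": np.concatenate([vis[:4], verb[:12]])}
    for k in range(3):
        blocks[f"cat{k}"] = np.concatenate(
            [vis[4 + 7 * k: 11 + 7 * k], verb[12 + 12 * k: 24 + 12 * k]]
        )
    return blocks


def _base_shape(category: str, animal_overlap: float) -> np.ndarray:
    """Uncalibrated activation-probability shape for one category.

    Own block 1.0, domain-shared 0.8 (echoing the template's quoted 80%
    presence probability for shared animal features), global block 0.9.
    Sibling-category overlap is asymmetric between the domains, mirroring
    the feature-norm structure both reference sets encode: animal
    categories share many properties (sibling weight 0.35, and the
    bird/mammal pair a higher ``animal_overlap``), while artefact
    categories are mutually distinctive (sibling weight 0.15).
    """
    domain = DOMAIN_OF[category]
    sibs = [c for c in CATEGORIES if DOMAIN_OF[c] == domain]
    blocks = _domain_slots(domain)
    shape = np.zeros(N_FEATURES)
    shape[_GLOBAL_SLOTS] = 0.9
    shape[blocks["shared"]] = 0.8
    for k, sib in enumerate(sibs):
        if sib == category:
            w = 1.0
        elif {category, sib} == {"birds", "mammals"}:
            w = animal_overlap
        elif domain == "animal":
            w = 0.45
        else:
            w = 0.15
        shape[blocks[f"cat{k}"]] = w
    return shape


def _calibrate(shape: np.ndarray, target_features: float) -> np.ndarray:
    """Scale ``shape`` so that sum(clip(alpha*shape, 0, 1)) == target_features."""
    nonzero = int(np.count_nonzero(shape))
    if target_features < 0 or target_features > nonzero:
        raise ValueError(
            f"target of {target_features} stochastic features not achievable "
            f"with {nonzero} available feature slots"
        )
    lo, hi = 0.0, 1.0
    while np.clip(hi * shape, 0, 1).sum() < target_features:
        hi *= 2
        if hi > 1e9:  # pragma: no cover - defensive
            raise ValueError("calibration failed to bracket the target")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.clip(mid * shape, 0, 1).sum() < target_features:
            lo = mid
        else:
            hi = mid
    return np.clip(0.5 * (lo + hi) * shape, 0, 1)


@dataclass(frozen=True)
class TemplateProfile:
    """Calibrated per-category activation probabilities for one pattern set."""

    profile_id: str
    probabilities: dict[str, np.ndarray]  # category -> (176,) in [0,1]
    target_means: dict[str, float]
    name_scheme: str = "paired-localist"

    def expected_feature_count(self, category: str) -> float:
        """Closed-form expected active units per item (name unit included)."""
        return 1.0 + float(self.probabilities[category].sum())

    def validate(self) -> None:
        cats = list(self.probabilities)
        if sorted(cats) != sorted(CATEGORIES):
            raise ValueError("profile must define all six categories")
        n_animal = sum(DOMAIN_OF[c] == "animal" for c in cats)
        if n_animal != 3:
            raise ValueError("expected exactly 3 animal and 3 artefact categories")
        for c, p in self.probabilities.items():
            if p.shape != (N_FEATURES,) or p.min() < 0 or p.max() > 1:
                raise ValueError(f"invalid probability vector for {c}")
            if abs(self.expected_feature_count(c) - self.target_means[c]) > 0.5:
                raise ValueError(f"calibration off target for {c}")


def build_profile(profile_id: str) -> TemplateProfile:
    """Build a calibrated template profile.

    ``"P1-like"`` reproduces the PDPTool pattern-set feature counts (and a
    tighter bird/mammal overlap); ``"P2-like"`` reproduces the counts of the
    probabilistic template.  Unknown ids raise :class:`UnknownProfileError`.
    """
    if profile_id == "P1-like":
        targets, overlap = P1_MEANS, 0.75
    elif profile_id == "P2-like":
        targets, overlap = P2_MEANS, 0.55
    else:
        raise UnknownProfileError(f"unknown profile id: {profile_id!r}")
    probs = {
        c: _calibrate(_base_shape(c, overlap), targets[c] - 1.0)
        for c in CATEGORIES
    }
    prof = TemplateProfile(profile_id, probs, dict(targets))
    prof.validate()
    return prof


def boost_domain_norms(
    profile: TemplateProfile, domain: str, target_mean: float
) -> TemplateProfile:
    """Rescale one domain's categories to a new expected feature count.

    Used to raise (or lower) the norms of, e.g., the animal vectors of a
    P2-like profile to P1-like levels while leaving the other domain's
    probabilities untouched.
    """
    if domain not in ("animal", "artefact"):
        raise ValueError(f"unknown domain: {domain!r}")
    probs = {}
    targets = dict(profile.target_means)
    for c in CATEGORIES:
        if DOMAIN_OF[c] == domain:
            probs[c] = _calibrate(profile.probabilities[c], target_mean - 1.0)
            targets[c] = float(target_mean)
        else:
            probs[c] = profile.probabilities[c].copy()
    boosted = TemplateProfile(
        f"{profile.profile_id}+{domain}@{target_mean:g}", probs, targets,
        profile.name_scheme,
    )
    boosted.validate()
    return boosted


@dataclass
class PatternSet:
    """48 binary items over 216 units with category/domain/name metadata."""

    vectors: np.ndarray  # (48, 216) uint8
    categories: list[str]
    domains: list[str]
    name_units: np.ndarray  # (48,) int, index into the name block
    seed: int
    profile_id: str = "custom"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.uint8)
        self.name_units = np.asarray(self.name_units, dtype=np.int64)
        if self.vectors.shape != (N_ITEMS, N_UNITS):
            raise ValueError(f"expected (48, 216) vectors, got {self.vectors.shape}")
        if not np.isin(self.vectors, (0, 1)).all():
            raise ValueError("pattern vectors must be strictly binary")
        for c in CATEGORIES:
            if self.categories.count(c) != ITEMS_PER_CATEGORY:
                raise ValueError(f"expected 8 items in category {c}")

    @property
    def name_block(self) -> np.ndarray:
        return self.vectors[:, :N_NAME]

    @property
    def visual_block(self) -> np.ndarray:
        return self.vectors[:, N_NAME:N_NAME + N_VISUAL]

    @property
    def verbal_block(self) -> np.ndarray:
        return self.vectors[:, N_NAME + N_VISUAL:]

    def domain_mask(self, domain: str) -> np.ndarray:
        return np.array([d == domain for d in self.domains])

    def feature_counts(self) -> np.ndarray:
        """Active units per item, over all 216 units."""
        return self.vectors.sum(axis=1)

    def category_mean_features(self) -> dict[str, float]:
        counts = self.feature_counts()
        cats = np.array(self.categories)
        return {c: float(counts[cats == c].mean()) for c in CATEGORIES}


def generate_patterns(profile: TemplateProfile, seed: int) -> PatternSet:
    """Sample a pattern set from a profile; identical seeds give identical sets.

    Each visual/verbal feature is drawn independently per item from its
    category's activation probability.  Name units follow a paired-localist
    scheme: the 48 items map onto the 40 name units with eight within-category
    item pairs sharing a unit (four categories contribute one shared pair and
    two contribute two, chosen with the set's seed).
    """
    profile.validate()
    rng = np.random.default_rng(seed)

    categories = [c for c in CATEGORIES for _ in range(ITEMS_PER_CATEGORY)]
    domains = [DOMAIN_OF[c] for c in categories]

    features = np.zeros((N_ITEMS, N_FEATURES), dtype=np.uint8)
    for k, c in enumerate(CATEGORIES):
        rows = slice(k * ITEMS_PER_CATEGORY, (k + 1) * ITEMS_PER_CATEGORY)
        p = profile.probabilities[c]
        features[rows] = rng.random((ITEMS_PER_CATEGORY, N_FEATURES)) < p

    # Name-unit allocation: category k receives n_k consecutive name units,
    # with (8 - n_k) shared pairs inside the category.
    units_per_cat = np.array([7, 7, 7, 7, 6, 6])
    rng.shuffle(units_per_cat)
    name_units = np.zeros(N_ITEMS, dtype=np.int64)
    next_unit = 0
    for k in range(len(CATEGORIES)):
        n_units = int(units_per_cat[k])
        n_pairs = ITEMS_PER_CATEGORY - n_units
        items = np.arange(ITEMS_PER_CATEGORY)
        rng.shuffle(items)
        assign = np.zeros(ITEMS_PER_CATEGORY, dtype=np.int64)
        # first 2*n_pairs shuffled items pair up; the rest get singleton units
        for j in range(n_pairs):
            assign[items[2 * j]] = assign[items[2 * j + 1]] = next_unit + j
        for j, it in enumerate(items[2 * n_pairs:]):
            assign[it] = next_unit + n_pairs + j
        name_units[k * ITEMS_PER_CATEGORY:(k + 1) * ITEMS_PER_CATEGORY] = assign
        next_unit += n_units

    vectors = np.zeros((N_ITEMS, N_UNITS), dtype=np.uint8)
    vectors[np.arange(N_ITEMS), name_units] = 1
    vectors[:, N_NAME:] = features
    return PatternSet(vectors, categories, domains, name_units, seed,
                      profile.profile_id)


@dataclass
class SimilaritySummary:
    correlation_matrix: np.ndarray  # (48, 48), nan where undefined
    per_category_mean_features: dict[str, float]
    block_means: dict[str, float]  # within_category / within_domain / cross_domain
    degenerate_items: list[int] = field(default_factory=list)


def similarity_summary(ps: PatternSet) -> SimilaritySummary:
    """Pearson correlations between full 216-unit item vectors, plus block means.

    Zero-variance items are flagged and their correlations reported as NaN.
    """
    x = ps.vectors.astype(float)
    sd = x.std(axis=1)
    degenerate = np.flatnonzero(sd == 0).tolist()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))

    cats = np.array(ps.categories)
    doms = np.array(ps.domains)
    same_cat = cats[:, None] == cats[None, :]
    same_dom = doms[:, None] == doms[None, :]
    off = ~np.eye(N_ITEMS, dtype=bool)

    def _mean(mask: np.ndarray) -> float:
        vals = corr[mask & off]
        return float(np.nanmean(vals)) if vals.size else float("nan")

    block_means = {
        "within_category": _mean(same_cat),
        "within_domain": _mean(same_dom & ~same_cat),
        "cross_domain": _mean(~same_dom),
    }
    return SimilaritySummary(corr, ps.category_mean_features(), block_means,
                             degenerate)


# ---------------------------------------------------------------------------
# File I/O: CSV of one row per item plus a JSON sidecar with metadata.
# ---------------------------------------------------------------------------

def write_patterns(path: str | Path, ps: PatternSet) -> None:
    path = Path(path)
    df = pd.DataFrame(ps.vectors, columns=[f"u{i:03d}" for i in range(N_UNITS)])
    df.insert(0, "name_unit", ps.name_units)
    df.insert(0, "domain", ps.domains)
    df.insert(0, "category", ps.categories)
    df.insert(0, "id", np.arange(N_ITEMS))
    df.to_csv(path, index=False)
    sidecar = {"profile_id": ps.profile_id, "seed": int(ps.seed),
               "schema": "lesionlab-patterns-v1"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_patterns(path: str | Path) -> PatternSet:
    path = Path(path)
    df = pd.read_csv(path)
    unit_cols = [c for c in df.columns if c.startswith("u")]
    if len(unit_cols) != N_UNITS:
        raise PatternFormatError(
            f"{path}: expected {N_UNITS} unit columns, found {len(unit_cols)}"
        )
    vals = df[unit_cols].to_numpy()
    bad = np.flatnonzero(~np.isin(vals, (0, 1)).all(axis=1))
    if bad.size:
        raise PatternFormatError(f"{path}: non-binary value in row {int(bad[0])}")
    meta = {"profile_id": "custom", "seed": -1}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return PatternSet(vals, df["category"].tolist(), df["domain"].tolist(),
                      df["name_unit"].to_numpy(), meta["seed"],
                      meta["profile_id"])


def read_pdptool_patterns(path: str | Path) -> np.ndarray:
    """Convenience importer for whitespace-delimited pattern files.

    Returns the raw (items x units) binary matrix; metadata (categories,
    name assignments) must be supplied separately.
    """
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        parts = line.split()
        if not parts:
            continue
        vals = [p for p in parts if p in ("0", "1")]
        if len(vals) != len([p for p in parts if _is_number(p)]):
            raise PatternFormatError(f"{path}: non-binary value on line {i + 1}")
        rows.append([int(v) for v in vals])
    return np.asarray(rows, dtype=np.uint8)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
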