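"""Survey data model, record classification, scoring and file I/O.

Repeated botanical site surveys produce long tables of recorded taxa. Each
record is classified against a site's accepted species list into one of four
categories:

``true_positive``
    a valid species on the site's accepted list;
``false_positive``
    a valid regional species that is not accepted at the site (a
    misidentification or reporting error);
``cautious``
    a record resolved only to genus — a deliberate choice by the observer,
    scored at half marks at most once per genus;
``mythical``
    a name that matches no valid taxon in the regional flora (an invented
    Latin combination, a misspelling with no synonym entry, ...).

Names are normalised (case, whitespace, authorship strings, infraspecific
epithets collapsed to the parent binomial) before matching; there is no fuzzy
matching, so anything that fails exact lookup is mythical unless a synonym
table resolves it.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, InputError, IntegrityError, ParseError

CATEGORIES = ("true_positive", "false_positive", "cautious", "mythical")

#: tokens that introduce an infraspecific epithet; everything from such a
#: token onward is dropped when collapsing to the parent binomial
_INFRASPECIFIC = {
    "subsp.", "subsp", "ssp.", "ssp", "var.", "var", "subvar.", "subvar",
    "f.", "forma", "nothosubsp.", "cv.",
}
_HYBRID_MARKS = {"x", "×"}


@dataclass(frozen=True)
class Observation:
    """One recorded taxon in one survey.

    ``category`` is ``None`` until :func:`classify_observation` has run.
    ``known_incorrect`` optionally distinguishes the "unreasonable or known
    incorrect" flavour of false positive; all analyses treat the two as one
    class.
    """

    survey_id: str
    raw_name: str
    matched_name: str | None = None
    rank: str = "species"
    category: str | None = None
    known_incorrect: bool = False

    def __post_init__(self) -> None:
        if self.rank not in ("species", "genus"):
            raise InputError(f"unknown rank {self.rank!r}")
        if self.category is not None and self.category not in CATEGORIES:
            raise InputError(f"unknown category {self.category!r}")


@dataclass
class Survey:
    """All observations made by one observer at one site on one date."""

    survey_id: str
    site_id: str
    observer_id: str
    date: str
    observations: list[Observation] = field(default_factory=list)

    def species_set(self, categories: Sequence[str] = ("true_positive", "false_positive")) -> set[str]:
        """Matched species-rank names in the given categories."""
        return {
            o.matched_name
            for o in self.observations
            if o.rank == "species" and o.matched_name and o.category in categories
        }

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for o in self.observations:
            if o.category is not None:
                counts[o.category] += 1
        return counts


@dataclass
class SiteReference:
    """Accepted species at a site plus the cumulative false-positive pool.

    ``accepted_species`` is the gold-standard observer's list merged with
    other reliable surveys of the site. ``fp_pool`` is every species ever
    recorded at the site as a false positive, across all surveys; it feeds
    the true-negative construction in the confusion calculus.
    """

    site_id: str
    accepted_species: frozenset[str]
    fp_pool: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.accepted_species = frozenset(self.accepted_species)
        self.fp_pool = frozenset(self.fp_pool)
        overlap = self.accepted_species & self.fp_pool
        if overlap:
            raise IntegrityError(
                f"site {self.site_id}: species both accepted and in fp_pool: {sorted(overlap)[:5]}"
            )


@dataclass(frozen=True)
class SpeciesAttributes:
    """Regional attributes of one species: its genus, the number of
    congeneric species in the regional flora, and the regional 4 km^2
    occupancy probability used as the rarity covariate."""

    species_name: str
    genus: str
    genus_size: int
    occupancy: float

    def __post_init__(self) -> None:
        if self.genus_size < 1:
            raise DomainError(f"{self.species_name}: genus_size must be >= 1")
        if not 0.0 <= self.occupancy <= 1.0:
            raise DomainError(f"{self.species_name}: occupancy must lie in [0, 1]")


@dataclass(frozen=True)
class SurveyScore:
    """Score of one survey against the gold-standard total.

    ``score`` = (true-positive species + 0.5 per distinct cautious genus −
    ``fp_penalty`` per false positive) / gold-standard total. The official
    grading penalised false positives by an unspecified amount, so the
    penalty weight defaults to zero and the count is reported separately.
    """

    score: float
    n_true_positive: int
    n_false_positive: int
    n_cautious_genera: int
    gold_total: int


# ---------------------------------------------------------------------------
# name normalisation and classification


def normalize_name(raw: str) -> tuple[str, str]:
    """Normalise a written taxon name; return ``(name, rank)``.

    Case-folds the genus, strips whitespace and authorship strings, drops
    hybrid signs, and collapses infraspecific records to the parent binomial.
    A name whose second token is not a lower-case epithet (e.g. ``"Carex"``
    or ``"Carex L."``) resolves to genus rank.
    """
    if not isinstance(raw, str):
        raise InputError(f"taxon name must be text, got {type(raw).__name__}")
    try:
        s = unicodedata.normalize("NFKC", raw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise InputError(f"unresolvable encoding in name {raw!r}") from exc
    tokens = [t for t in s.strip().split() if t not in _HYBRID_MARKS]
    if not tokens:
        raise InputError("empty taxon name")
    genus = tokens[0][:1].upper() + tokens[0][1:].lower()
    epithet = None
    for tok in tokens[1:]:
        low = tok.lower()
        if low in _INFRASPECIFIC:
            break
        if tok[:1].islower() and low.replace("-", "").isalpha():
            epithet = low
            break
        # capitalised / punctuated token = start of an authorship string
        break
    if epithet is None:
        return genus, "genus"
    return f"{genus} {epithet}", "species"


def classify_observation(
    raw_name: str,
    ref: SiteReference,
    regional_checklist: set[str],
    genus_index: set[str],
    *,
    survey_id: str = "",
    synonyms: Mapping[str, str] | None = None,
) -> Observation:
    """Classify one written record into exactly one of the four categories.

    Classification is total: every record receives a category. Genus-rank
    names found in ``genus_index`` are cautious; names absent from both the
    regional checklist and the genus index are mythical (``matched_name``
    absent); valid species are true positives when accepted at the site and
    false positives otherwise.
    """
    name, rank = normalize_name(raw_name)
    if synonyms:
        name = synonyms.get(name, name)
        if " " in name:
            rank = "species"
    if rank == "genus":
        if name in genus_index:
            return Observation(survey_id, raw_name, name, "genus", "cautious")
        return Observation(survey_id, raw_name, None, "genus", "mythical")
    if name not in regional_checklist:
        return Observation(survey_id, raw_name, None, "species", "mythical")
    if name in ref.accepted_species:
        return Observation(survey_id, raw_name, name, "species", "true_positive")
    return Observation(survey_id, raw_name, name, "species", "false_positive")


def classify_survey(
    survey: Survey,
    ref: SiteReference,
    regional_checklist: set[str],
    genus_index: set[str],
    synonyms: Mapping[str, str] | None = None,
) -> Survey:
    """Classify every observation of a survey; duplicate species records
    (after normalisation) collapse to a single record."""
    seen_species: set[str] = set()
    out: list[Observation] = []
    for obs in survey.observations:
        cls = classify_observation(
            obs.raw_name, ref, regional_checklist, genus_index,
            survey_id=survey.survey_id, synonyms=synonyms,
        )
        if cls.rank == "species" and cls.matched_name:
            if cls.matched_name in seen_species:
                continue
            seen_species.add(cls.matched_name)
        out.append(cls)
    return replace_observations(survey, out)


def replace_observations(survey: Survey, observations: list[Observation]) -> Survey:
    return Survey(survey.survey_id, survey.site_id, survey.observer_id, survey.date, observations)


def build_fp_pool(surveys: Iterable[Survey]) -> frozenset[str]:
    """Cumulative pool of species ever recorded as false positives.

    Equals the union of per-survey false-positive species sets, and is
    therefore non-decreasing as surveys are added.
    """
    pool: set[str] = set()
    for s in surveys:
        pool |= s.species_set(("false_positive",))
    return frozenset(pool)


def build_site_reference(site_id: str, accepted_species: Iterable[str], classified_surveys: Iterable[Survey] = ()) -> SiteReference:
    """Assemble a :class:`SiteReference`, deriving ``fp_pool`` from the full
    classified record set for the site."""
    return SiteReference(site_id, frozenset(accepted_species), build_fp_pool(classified_surveys))


def score_survey(survey: Survey, gold_total: int, fp_penalty: float = 0.0) -> SurveyScore:
    """Score a classified survey as a fraction of the gold-standard total.

    Correct species count one mark; a cautious (genus-only) record earns half
    a mark but only once per genus; false positives are reported as a count
    and subtract ``fp_penalty`` marks each (default 0: reported, unweighted).
    """
    if gold_total <= 0:
        raise DomainError(f"gold_total must be positive, got {gold_total}")
    counts = survey.category_counts()
    cautious_genera = {
        o.matched_name for o in survey.observations if o.category == "cautious"
    }
    n_tp = counts["true_positive"]
    n_fp = counts["false_positive"]
    score = (n_tp + 0.5 * len(cautious_genera) - fp_penalty * n_fp) / gold_total
    return SurveyScore(score, n_tp, n_fp, len(cautious_genera), gold_total)


# ---------------------------------------------------------------------------
# file I/O

SURVEY_COLUMNS = ("site_id", "survey_id", "observer_id", "date", "raw_name", "rank")
CLASSIFIED_COLUMNS = SURVEY_COLUMNS + ("matched_name", "category")


def _read_table(path, sep: str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)


def _apply_colmap(df: pd.DataFrame, colmap: Mapping[str, str] | None) -> pd.DataFrame:
    """Adapter for foreign layouts: ``colmap`` maps canonical column names to
    the names actually present in the file."""
    if colmap:
        df = df.rename(columns={v: k for k, v in colmap.items()})
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def read_surveys(path, colmap: Mapping[str, str] | None = None, sep: str | None = None) -> list[Survey]:
    """Read a long-format survey table: one row per observation.

    Canonical columns: site_id, survey_id, observer_id, date (ISO-8601),
    raw_name and optionally rank (inferred from the name when absent). A
    survey_id appearing under two sites or observers is an integrity error.
    """
    df = _apply_colmap(_read_table(path, sep), colmap)
    _require_columns(df, [c for c in SURVEY_COLUMNS if c != "rank"], path)
    has_cls = all(c in df.columns for c in ("matched_name", "category"))
    surveys: dict[str, Survey] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        for col in ("site_id", "survey_id", "observer_id", "raw_name"):
            if not rec[col]:
                raise ParseError(f"{path}: row {i}: missing value in column {col!r}")
        sid = rec["survey_id"]
        sv = surveys.get(sid)
        if sv is None:
            sv = surveys[sid] = Survey(sid, rec["site_id"], rec["observer_id"], rec.get("date", ""))
        elif (sv.site_id, sv.observer_id) != (rec["site_id"], rec["observer_id"]):
            raise IntegrityError(
                f"{path}: row {i}: survey_id {sid!r} reused across sites/observers"
            )
        rank = rec.get("rank") or normalize_name(rec["raw_name"])[1]
        if has_cls:
            obs = Observation(
                sid, rec["raw_name"], rec["matched_name"] or None, rank,
                rec["category"] or None,
            )
        else:
            obs = Observation(sid, rec["raw_name"], rank=rank)
        sv.observations.append(obs)
    return list(surveys.values())


def surveys_to_frame(surveys: Iterable[Survey]) -> pd.DataFrame:
    """Flatten surveys to a tidy long table (classification columns included
    when present)."""
    rows = []
    for s in surveys:
        for o in s.observations:
            rows.append(
                {
                    "site_id": s.site_id,
                    "survey_id": s.survey_id,
                    "observer_id": s.observer_id,
                    "date": s.date,
                    "raw_name": o.raw_name,
                    "rank": o.rank,
                    "matched_name": o.matched_name or "",
                    "category": o.category or "",
                }
            )
    return pd.DataFrame(rows, columns=list(CLASSIFIED_COLUMNS))


def write_surveys(surveys: Iterable[Survey], path, sep: str = ",") -> None:
    surveys_to_frame(surveys).to_csv(path, sep=sep, index=False)


def read_reference_lists(path, sep: str | None = None) -> dict[str, set[str]]:
    """Two-column table (site_id, species) -> accepted species per site."""
    df = _read_table(path, sep)
    _require_columns(df, ["site_id", "species"], path)
    out: dict[str, set[str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if not row.site_id or not row.species:
            raise ParseError(f"{path}: row {i}: missing site_id or species")
        out.setdefault(row.site_id, set()).add(normalize_name(row.species)[0])
    return out


def read_species_attributes(path, sep: str | None = None) -> pd.DataFrame:
    """Four-column table (species_name, genus, genus_size, occupancy) as a
    DataFrame indexed by species name; values validated."""
    df = _read_table(path, sep)
    _require_columns(df, ["species_name", "genus", "genus_size", "occupancy"], path)
    try:
        df["genus_size"] = df["genus_size"].astype(int)
        df["occupancy"] = df["occupancy"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric genus_size or occupancy: {exc}") from exc
    if (df["genus_size"] < 1).any():
        bad = df.index[df["genus_size"] < 1][0]
        raise ParseError(f"{path}: row {bad + 2}: genus_size < 1")
    if ((df["occupancy"] < 0) | (df["occupancy"] > 1)).any():
        bad = df.index[(df["occupancy"] < 0) | (df["occupancy"] > 1)][0]
        raise ParseError(f"{path}: row {bad + 2}: occupancy outside [0, 1]")
    return df.set_index("species_name")


def checklist_from_attributes(attrs: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Derive the regional species checklist and genus index from a species
    attribute table."""
    species = set(attrs.index)
    genera = set(attrs["genus"]) | {s.split()[0] for s in species}
    return species, genera


def read_newick(path):
    """Read a rooted Newick phylogeny (branch lengths preserved).

    Thin wrapper over :func:`surveyerr.phylo_signal.PhyloTree.from_newick`.
    """
    from .phylo_signal import PhyloTree

    return PhyloTree.from_newick(path)
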