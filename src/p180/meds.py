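"""Free-text medication entries -> subject x drug-class Boolean matrix.

Mirrors the curation route used for cohort confounder control: raw entries
("Aricept 10mg QD", "lisinopril/HCTZ 20-12.5") are normalized into drug-name
tokens, matched against a lexicon of brand and generic names by approximate
string similarity, low-scoring matches are queued for manual review, and
accepted names are rolled up name -> ingredient(s) -> drug class(es) from
standard terminologies (ATC, NDF-RT, MeSH, DailyMed/FDA SPL). Each subject
then gets one Boolean flag per class.

The matcher is a pluggable contract: score 1.0 for an exact normalized
match, symmetric, decreasing in edit distance. The default backend is
normalized Levenshtein similarity (1 - distance / max length) computed with
edlib. Thresholds (auto-accept >= 0.85, manual review >= 0.5) are
configuration, not reconstructions of any published cutoff.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import edlib
import pandas as pd
import yaml


# --------------------------------------------------------------------------
# lexicon

@dataclass
class TermLexicon:
    """Drug-name lexicon: name -> ingredients, ingredient -> classes."""

    entries: dict  # normalized name (brand or generic) -> [ingredient, ...]
    ingredient_classes: dict  # ingredient -> [(class_name, source), ...]

    def __post_init__(self):
        for name, ingredients in self.entries.items():
            for ing in ingredients:
                if ing not in self.ingredient_classes:
                    raise ValueError(
                        f"lexicon name {name!r} references ingredient {ing!r} "
                        "with no class entry (use an empty list for class-free)"
                    )

    @property
    def names(self) -> list:
        return sorted(self.entries)

    def class_list(self) -> list:
        out = set()
        for pairs in self.ingredient_classes.values():
            out.update(c for c, _ in pairs)
        return sorted(out)

    def classes_of(self, name: str) -> set:
        out = set()
        for ing in self.entries[name]:
            out.update(c for c, _ in self.ingredient_classes[ing])
        return out

    @classmethod
    def from_yaml(cls, path) -> "TermLexicon":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls._from_raw(raw)

    @classmethod
    def _from_raw(cls, raw: dict) -> "TermLexicon":
        entries = {str(k).lower(): list(v) for k, v in raw["names"].items()}
        classes = {
            ing: [(str(c), str(s)) for c, s in pairs]
            for ing, pairs in raw["ingredient_classes"].items()
        }
        return cls(entries, classes)

    @classmethod
    def default(cls) -> "TermLexicon":
        """The bundled offline lexicon (~55 drugs spanning the class list)."""
        ref = importlib.resources.files("p180").joinpath("data/lexicon.yaml")
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
        return cls._from_raw(raw)


# --------------------------------------------------------------------------
# normalization

_UNIT_WORDS = {
    "mg", "mcg", "ug", "g", "kg", "ml", "l", "cc", "iu", "meq", "mmol",
    "unit", "units", "tab", "tabs", "tablet", "tablets", "cap", "caps",
    "capsule", "capsules", "pill", "pills", "puff", "puffs", "drop",
    "drops", "patch", "spray", "gtt",
}
_FREQ_WORDS = {
    "qd", "od", "bid", "tid", "qid", "qhs", "qam", "qpm", "hs", "prn",
    "po", "o", "daily", "weekly", "nightly", "oral", "orally", "topical",
    "am", "pm", "x",
}
# a number, optionally a range (20-12.5), optionally glued to a unit (10mg)
_NUM_TOKEN = re.compile(
    r"^\d+(\.\d+)?(-\d+(\.\d+)?)*(%|" + "|".join(sorted(_UNIT_WORDS)) + r")?$"
)
_SEPARATORS = re.compile(r"/|\+|\bwith\b|,|;|&")
_PUNCT = re.compile(r"[()\[\]{}:!?#*]")


def normalize_med_text(raw_text: str) -> list:
    """Lowercased drug-name tokens with dose/route/frequency noise removed.

    Combination separators ("/", "+", " with ", commas) split the entry into
    multiple tokens. Returns [] when nothing resembling a name survives.
    """
    if not str(raw_text).strip():
        raise ValueError("empty medication text")
    text = str(raw_text).lower()
    text = _PUNCT.sub(" ", text)
    parts = _SEPARATORS.split(text)
    tokens = []
    for part in parts:
        words = [w for w in re.split(r"\s+", part.strip()) if w]
        kept = [
            w
            for w in words
            if not _NUM_TOKEN.match(w) and w not in _UNIT_WORDS and w not in _FREQ_WORDS
        ]
        if kept:
            tokens.append(" ".join(kept))
    return tokens


# --------------------------------------------------------------------------
# matching

class LevenshteinMatcher:
    """Normalized Levenshtein similarity: 1 - edit distance / max length."""

    def score(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        if not a or not b:
            return 0.0
        dist = edlib.align(a, b)["editDistance"]
        return 1.0 - dist / max(len(a), len(b))


STATUS_AUTO = "auto_accepted"
STATUS_REVIEW = "needs_review"
STATUS_REJECTED = "rejected"
STATUS_MANUAL = "manually_adjusted"


@dataclass
class MatchThresholds:
    accept: float = 0.85
    review: float = 0.50

    def __post_init__(self):
        if not 0 <= self.review <= self.accept <= 1:
            raise ValueError("need 0 <= review <= accept <= 1")


@dataclass
class MatchCandidate:
    query: str
    candidate: str
    score: float
    status: str


def match_term(
    token: str,
    lexicon: TermLexicon,
    matcher=None,
    thresholds: MatchThresholds | None = None,
) -> list:
    """Ranked MatchCandidates for one normalized token.

    Sorted by score descending, ties broken lexicographically; statuses come
    from the thresholds (only the top candidate can be auto-accepted or
    queued for review — the rest are context)."""
    matcher = matcher or LevenshteinMatcher()
    thresholds = thresholds or MatchThresholds()
    scored = sorted(
        ((matcher.score(token, name), name) for name in lexicon.names),
        key=lambda t: (-t[0], t[1]),
    )
    out = []
    for rank, (score, name) in enumerate(scored):
        if rank == 0 and score >= thresholds.accept:
            status = STATUS_AUTO
        elif rank == 0 and score >= thresholds.review:
            status = STATUS_REVIEW
        else:
            status = STATUS_REJECTED
        out.append(MatchCandidate(token, name, score, status))
    return out


def classify_entries(
    meds: pd.DataFrame,
    lexicon: TermLexicon,
    matcher=None,
    thresholds: MatchThresholds | None = None,
) -> pd.DataFrame:
    """Match every entry's tokens; one row per (subject, raw_text, token).

    ``meds`` needs columns subject_id and raw_text (a visit column is
    carried through if present). Unparseable entries (nothing left after
    normalization) yield a row with status ``rejected`` and no token.
    """
    rows = []
    for rec in meds.itertuples(index=False):
        raw = str(rec.raw_text)
        if not raw.strip():
            continue
        tokens = normalize_med_text(raw)
        if not tokens:
            rows.append(
                {"subject_id": rec.subject_id, "raw_text": raw, "token": "",
                 "candidate": "", "score": 0.0, "status": STATUS_REJECTED}
            )
            continue
        for tok in tokens:
            cands = match_term(tok, lexicon, matcher, thresholds)
            top = cands[0] if cands else MatchCandidate(tok, "", 0.0, STATUS_REJECTED)
            rows.append(
                {"subject_id": rec.subject_id, "raw_text": raw, "token": tok,
                 "candidate": top.candidate, "score": top.score, "status": top.status}
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "raw_text", "token", "candidate", "score", "status"]
    )


def apply_review(match_table: pd.DataFrame, review: pd.DataFrame) -> pd.DataFrame:
    """Apply serialized manual decisions to the needs_review rows.

    ``review`` needs columns ``query`` (the normalized token), ``action``
    (``accept_as`` or ``reject``) and ``target`` (lexicon name for
    accept_as). Reviewing a token that is not queued — unknown, or already
    auto-accepted — rejects the whole file: decisions must be reproducible
    against the exact queue they answered.
    """
    out = match_table.copy()
    queued = set(out.loc[out["status"] == STATUS_REVIEW, "token"])
    auto = set(out.loc[out["status"] == STATUS_AUTO, "token"])
    for rec in review.itertuples(index=False):
        q = str(rec.query)
        if q in auto and q not in queued:
            raise ValueError(f"review file touches auto-accepted term {q!r}")
        if q not in queued:
            raise ValueError(f"review file references unknown query {q!r}")
        mask = (out["token"] == q) & (out["status"] == STATUS_REVIEW)
        if rec.action == "accept_as":
            target = str(rec.target)
            out.loc[mask, "candidate"] = target
            out.loc[mask, "status"] = STATUS_MANUAL
            out.loc[mask, "manual_accept"] = True
        elif rec.action == "reject":
            out.loc[mask, "status"] = STATUS_MANUAL
            out.loc[mask, "manual_accept"] = False
        else:
            raise ValueError(f"unknown review action {rec.action!r}")
    if "manual_accept" not in out.columns:
        out["manual_accept"] = pd.NA
    return out


def _accepted_rows(match_table: pd.DataFrame) -> pd.DataFrame:
    man = match_table.get("manual_accept")
    accepted = match_table["status"] == STATUS_AUTO
    if man is not None:
        accepted |= (match_table["status"] == STATUS_MANUAL) & (man == True)  # noqa: E712
    return match_table[accepted]


def map_to_classes(
    match_table: pd.DataFrame,
    lexicon: TermLexicon,
    class_list: list | None = None,
    all_subjects=None,
) -> pd.DataFrame:
    """Boolean subject x drug-class matrix from the accepted matches.

    Subjects with zero accepted entries appear as all-False rows; classes
    outside ``class_list`` are ignored; an ingredient with no class entry
    contributes nothing.
    """
    classes = sorted(class_list) if class_list is not None else lexicon.class_list()
    if not classes:
        raise ValueError("class list is empty")
    subjects = sorted(
        set(match_table["subject_id"]) | set(all_subjects if all_subjects is not None else [])
    )
    mat = pd.DataFrame(False, index=pd.Index(subjects, name="subject_id"), columns=classes)
    for rec in _accepted_rows(match_table).itertuples(index=False):
        if rec.candidate not in lexicon.entries:
            raise ValueError(f"accepted candidate {rec.candidate!r} not in lexicon")
        for cls_name in lexicon.classes_of(rec.candidate):
            if cls_name in mat.columns:
                mat.loc[rec.subject_id, cls_name] = True
    return mat


def run_med_pipeline(
    meds: pd.DataFrame,
    lexicon: TermLexicon | None = None,
    review: pd.DataFrame | None = None,
    matcher=None,
    thresholds: MatchThresholds | None = None,
    class_list: list | None = None,
):
    """End-to-end: normalize, match, review, roll up. Returns (matrix, table)."""
    lexicon = lexicon or TermLexicon.default()
    table = classify_entries(meds, lexicon, matcher, thresholds)
    if review is not None and len(review):
        table = apply_review(table, review)
    matrix = map_to_classes(
        table, lexicon, class_list, all_subjects=meds["subject_id"].unique()
    )
    return matrix, table
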