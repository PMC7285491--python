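"""Small built-in lexicons for the engineered baseline features.

The original study counted medical-term mentions with an external clinical
tagger; here a flat term lexicon stands behind the same feature, and any
user-supplied lexicon can replace it. Polarity uses a simple
positive/negative word-count scorer over the lexicons below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

DEFAULT_BIBLIOGRAPHY_KEYWORDS = frozenset(
    {"references", "bibliography", "sources", "citations"}
)

# Flat medical-term lexicon (lowercased, single words and short phrases).
DEFAULT_MEDICAL_TERMS = frozenset({
    "cancer", "tumor", "tumour", "chemotherapy", "radiotherapy", "radiation",
    "surgery", "biopsy", "mastectomy", "lymph", "metastasis", "oncology",
    "arthritis", "rheumatoid", "inflammation", "joint", "cartilage",
    "nsaid", "nsaids", "corticosteroid", "synovial", "osteoarthritis",
    "depression", "antidepressant", "ssri", "ssris", "psychotherapy",
    "serotonin", "anxiety", "therapy", "diagnosis", "prognosis", "symptom",
    "symptoms", "treatment", "medication", "medicine", "dose", "dosage",
    "clinical", "patient", "physician", "hormone", "immune", "infection",
    "enzyme", "drug", "vaccine", "screening", "relapse", "remission",
})

DEFAULT_POSITIVE_WORDS = frozenset({
    "improve", "improved", "improvement", "benefit", "benefits", "effective",
    "safe", "success", "successful", "relief", "better", "helpful", "heal",
    "recovery", "recover", "good", "well", "gain", "positive", "support",
})

DEFAULT_NEGATIVE_WORDS = frozenset({
    "risk", "risks", "harm", "harmful", "severe", "serious", "pain",
    "painful", "adverse", "worse", "worsen", "death", "dangerous", "damage",
    "toxic", "negative", "complication", "complications", "fatigue", "nausea",
})


@dataclass(frozen=True)
class LexiconSet:
    bibliography_keywords: frozenset[str] = DEFAULT_BIBLIOGRAPHY_KEYWORDS
    medical_terms: frozenset[str] = DEFAULT_MEDICAL_TERMS
    positive_words: frozenset[str] = DEFAULT_POSITIVE_WORDS
    negative_words: frozenset[str] = DEFAULT_NEGATIVE_WORDS

    @classmethod
    def from_files(cls, medical_terms_path: str | Path | None = None,
                   **overrides) -> "LexiconSet":
        """Load the medical-term lexicon from a plain-text file (one term
        per line, '#' comments); other lexicons overridable by keyword."""
        from .errors import ConfigError

        kwargs = dict(overrides)
        if medical_terms_path is not None:
            path = Path(medical_terms_path)
            if not path.exists():
                raise ConfigError(f"lexicon file not found: {path}")
            terms = {
                line.strip().lower()
                for line in path.read_text(encoding="utf-8").splitlines()
                if line.strip() and not line.startswith("#")
            }
            kwargs["medical_terms"] = frozenset(terms)
        return cls(**kwargs)
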