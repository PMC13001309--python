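"""Description augmentation via a pluggable text-completion backend.

Raw human descriptions (HD) and label sets (HL, machine labels) are
completed into full sentences (CHD/CHL/CDL); SMILES zero/few-shot prompts
are assembled for external language models.  The prompt templates shipped
here are plain-text reconstructions with sensible defaults, not verbatim
copies of any external prompt.  A deterministic template backend serves
tests and offline runs; network-backed completion engines plug in through
the same one-callable interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from odieu.catalog import DescriptionKind, DescriptionRecord, normalize_text
from odieu.lexical import STOPWORDS, tokenize

#: output kind by input kind for sentence completion
COMPLETION_KIND = {
    DescriptionKind.HD: DescriptionKind.CHD,
    DescriptionKind.HL: DescriptionKind.CHL,
    DescriptionKind.CDL: DescriptionKind.CDL,   # machine labels -> completed sentence
}

DEFAULT_TEMPLATES = {
    "complete_description": (
        "Rewrite the following odor notes as one complete sentence describing "
        "the smell, keeping every descriptive word: {content}"
    ),
    "labels_to_sentence": (
        "Write one complete sentence describing a smell with exactly these "
        "qualities: {content}"
    ),
    "smiles_describe": (
        "Describe the odor of the molecule with SMILES {smiles} in one sentence."
    ),
}


@dataclass
class PromptTemplate:
    task: str
    template: str
    n_shot: int = 0

    def fill(self, **slots) -> str:
        return self.template.format(**slots)


class CompletionError(RuntimeError):
    pass


@dataclass
class TemplateBackend:
    """Deterministic completion engine: wraps the content words into the
    canonical sentence frame.  Used offline and in tests."""

    name: str = "deterministic-template"

    def __call__(self, prompt: str, content_words: Sequence[str]) -> str:
        if not content_words:
            raise CompletionError("no content words to complete")
        if len(content_words) == 1:
            joined = content_words[0]
        else:
            joined = ", ".join(content_words[:-1]) + ", " + content_words[-1]
        return f"This molecule has a {joined} odor."


def _content_words(record: DescriptionRecord) -> list[str]:
    if record.kind is DescriptionKind.HL or record.labels:
        return [t for lab in (record.labels or ()) for t in tokenize(lab)]
    return [t for t in tokenize(record.text) if t not in STOPWORDS]


def complete_description(
    record: DescriptionRecord,
    backend: Callable[[str, Sequence[str]], str] = TemplateBackend(),
    templates: dict[str, str] = DEFAULT_TEMPLATES,
    retries: int = 2,
) -> DescriptionRecord:
    """Complete an HD/HL/machine-label record into a full sentence record.

    The output must contain every input content word; a missing word after
    retries raises a validation warning on the returned record's behalf.
    The original record is never overwritten: the result is a new record of
    the completed kind.
    """
    if record.kind not in COMPLETION_KIND:
        raise ValueError(f"cannot complete records of kind {record.kind.value}")
    words = _content_words(record)
    if not words:
        raise ValueError("record has no content words / labels to complete")
    task = "labels_to_sentence" if record.kind is DescriptionKind.HL else "complete_description"
    prompt = PromptTemplate(task, templates[task]).fill(content=", ".join(words))
    last_exc: Optional[Exception] = None
    for _ in range(retries + 1):
        try:
            text = normalize_text(backend(prompt, words))
            break
        except CompletionError as exc:
            last_exc = exc
    else:
        raise CompletionError(f"backend failed after {retries + 1} attempts") from last_exc
    out_tokens = set(tokenize(text))
    missing = [w for w in words if w not in out_tokens]
    if missing:
        warnings.warn(f"completion for {record.molecule_id}/{record.source} "
                      f"is missing input labels {missing}")
    return DescriptionRecord(
        molecule_id=record.molecule_id,
        source=record.source,
        kind=COMPLETION_KIND[record.kind],
        text=text,
        labels=record.labels,
    )


class LeakageError(ValueError):
    pass


def fewshot_smiles_prompt(
    query_smiles: str,
    examples: Sequence[tuple[str, str]],
    n_shot: int = 0,
    seed: int = 0,
    templates: dict[str, str] = DEFAULT_TEMPLATES,
) -> str:
    """Assemble a zero/few-shot SMILES-to-description prompt.

    ``n_shot`` example blocks are selected by seeded sampling without
    replacement; the query molecule must not appear among the examples
    (leakage guard).
    """
    if any(s == query_smiles for s, _ in examples):
        raise LeakageError(f"query SMILES {query_smiles!r} present in example pool")
    if not 0 <= n_shot <= len(examples):
        raise ValueError(f"n_shot={n_shot} outside [0, {len(examples)}]")
    rng = np.random.default_rng(seed)
    chosen = [examples[i] for i in sorted(rng.choice(len(examples), size=n_shot,
                                                     replace=False))] if n_shot else []
    blocks = [f"SMILES: {s}\nDescription: {t}" for s, t in chosen]
    query = PromptTemplate("smiles_describe",
                           templates["smiles_describe"]).fill(smiles=query_smiles)
    return "\n\n".join([*blocks, query])
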