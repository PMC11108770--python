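"""Template tokenizer for echocardiography report text.

Clinical echo reports are produced by filling a fixed institutional template,
so nearly all sentences are instances of a small set of slotted phrases
("Moderate left ventricular hypertrophy.", "Left ventricular ejection
fraction is 60%."). The tokenizer exploits this: each template is matched by
a regular expression with typed slots and emits one template token plus one
token per slot — a SEVERITY token for graded terms and a NUMBER token whose
literal numeric value is carried out-of-band in the token sequence. This
compresses a report by roughly an order of magnitude relative to subword
tokenization, which is what lets a whole report fit into a modest
transformer context.

Token id layout: PAD=0, UNK=1, NUM=2, severity tokens from 3, template ids
contiguous from TEMPLATE_OFFSET.
"""
from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field

import yaml

PAD_ID = 0
UNK_ID = 1
NUM_ID = 2
SEVERITY_OFFSET = 3
TEMPLATE_OFFSET = 32

DEFAULT_SEVERITY_TOKENS = ("mild", "moderate", "severe", "small", "large")

_NUMBER_RE = r"(\d+(?:\.\d+)?)"
_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")


@dataclass(frozen=True)
class TemplateEntry:
    """One slotted phrase pattern.

    ``canonical_form`` uses ``_`` for each slot; ``slots`` lists the slot
    types in order (``SEVERITY`` or ``NUMBER``), with an optional unit
    annotation for numbers (display only — the unit text is part of the
    canonical form).
    """
    template_id: int
    canonical_form: str
    slots: tuple[str, ...]
    units: tuple[str, ...] = ()

    def compile(self, severity_tokens: tuple[str, ...]) -> re.Pattern:
        sev = "|".join(re.escape(s) for s in severity_tokens)
        parts = self.canonical_form.split("_")
        if len(parts) - 1 != len(self.slots):
            raise ValueError(
                f"template {self.template_id!r}: {len(parts) - 1} placeholders "
                f"but {len(self.slots)} slots: {self.canonical_form!r}")
        out = [re.escape(parts[0])]
        for slot, lit in zip(self.slots, parts[1:]):
            out.append(f"({sev})" if slot == "SEVERITY" else _NUMBER_RE)
            out.append(re.escape(lit))
        return re.compile("".join(out), re.IGNORECASE)


@dataclass
class TemplateVocabulary:
    entries: list[TemplateEntry]
    severity_tokens: tuple[str, ...] = DEFAULT_SEVERITY_TOKENS
    number_encoding: str = "single-NUM-token, literal value carried out-of-band"
    _patterns: list[re.Pattern] = field(default_factory=list, repr=False)

    def __post_init__(self):
        self._patterns = [e.compile(self.severity_tokens) for e in self.entries]
        # longest canonical form first so more specific templates win
        self._order = sorted(range(len(self.entries)),
                             key=lambda i: -len(self.entries[i].canonical_form))

    @property
    def size(self) -> int:
        """Vocabulary size: templates plus special and severity tokens."""
        return len(self.entries) + 3 + len(self.severity_tokens)

    def severity_id(self, word: str) -> int:
        return SEVERITY_OFFSET + self.severity_tokens.index(word.lower())

    def severity_word(self, token_id: int) -> str:
        return self.severity_tokens[token_id - SEVERITY_OFFSET]

    def entry_by_id(self, template_id: int) -> TemplateEntry:
        idx = template_id - TEMPLATE_OFFSET
        if not 0 <= idx < len(self.entries):
            raise KeyError(f"unknown template id {template_id}")
        return self.entries[idx]

    def max_token_id(self) -> int:
        return TEMPLATE_OFFSET + len(self.entries)

    # ---- serialization --------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "severity_tokens": list(self.severity_tokens),
            "number_encoding": self.number_encoding,
            "entries": [
                {"template_id": e.template_id, "canonical_form": e.canonical_form,
                 "slots": list(e.slots), "units": list(e.units)}
                for e in self.entries],
        }, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "TemplateVocabulary":
        d = json.loads(s)
        entries = [TemplateEntry(e["template_id"], e["canonical_form"],
                                 tuple(e["slots"]), tuple(e["units"]))
                   for e in d["entries"]]
        return cls(entries=entries, severity_tokens=tuple(d["severity_tokens"]),
                   number_encoding=d["number_encoding"])

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TemplateVocabulary":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def __eq__(self, other):
        return isinstance(other, TemplateVocabulary) and self.to_json() == other.to_json()


@dataclass
class TokenSequence:
    """An encoded report: token ids plus out-of-band slot values.

    ``slot_values`` holds ``(position, slot_type, value)`` triples aligned to
    positions in ``tokens``; NUMBER values are floats, SEVERITY values the
    lowercase grade word.
    """
    tokens: list[int]
    slot_values: list[tuple[int, str, object]]

    @property
    def length(self) -> int:
        return len(self.tokens)

    def truncate(self, n: int) -> "TokenSequence":
        return TokenSequence(self.tokens[:n],
                             [sv for sv in self.slot_values if sv[0] < n])

    def window(self, start: int, n: int) -> "TokenSequence":
        toks = self.tokens[start:start + n]
        svs = [(p - start, t, v) for p, t, v in self.slot_values
               if start <= p < start + n]
        return TokenSequence(toks, svs)

    def __eq__(self, other):
        return (isinstance(other, TokenSequence) and self.tokens == other.tokens
                and self.slot_values == other.slot_values)


def build_vocabulary(grammar) -> TemplateVocabulary:
    """Build a TemplateVocabulary from a grammar file (YAML/JSON) or dict.

    The grammar is a mapping with optional ``severity_tokens`` and a
    ``templates`` list of ``{canonical_form, slots, units}`` records. Ids are
    assigned contiguously from TEMPLATE_OFFSET in file order, so a given
    grammar always produces the same vocabulary.
    """
    if isinstance(grammar, (str, bytes)) or hasattr(grammar, "read") or hasattr(grammar, "open"):
        with open(grammar) as fh:
            spec = yaml.safe_load(fh)
    else:
        spec = grammar
    severity = tuple(spec.get("severity_tokens", DEFAULT_SEVERITY_TOKENS))
    seen: dict[str, int] = {}
    collisions = []
    entries = []
    for i, t in enumerate(spec["templates"]):
        cf = t["canonical_form"]
        if cf in seen:
            collisions.append(cf)
            continue
        seen[cf] = i
        entries.append(TemplateEntry(
            template_id=TEMPLATE_OFFSET + len(entries),
            canonical_form=cf,
            slots=tuple(t.get("slots", ())),
            units=tuple(t.get("units", ()))))
    if collisions:
        raise ValueError(f"duplicate canonical forms: {sorted(set(collisions))}")
    return TemplateVocabulary(entries=entries, severity_tokens=severity)


def _split_sentences(text: str) -> list[str]:
    return [s.strip() for s in _SENTENCE_SPLIT.split(text.strip()) if s.strip()]


def tokenize(report: str, vocab: TemplateVocabulary) -> TokenSequence:
    """Encode a report: one template token + slot tokens per matched sentence,
    one UNK per unmatched sentence. Matching is case-insensitive, full-sentence,
    longest template first."""
    tokens: list[int] = []
    slot_values: list[tuple[int, str, object]] = []
    for sentence in _split_sentences(report):
        matched = False
        for idx in vocab._order:
            m = vocab._patterns[idx].fullmatch(sentence)
            if m is None:
                continue
            entry = vocab.entries[idx]
            tokens.append(entry.template_id)
            for slot, raw in zip(entry.slots, m.groups()):
                pos = len(tokens)
                if slot == "SEVERITY":
                    tokens.append(vocab.severity_id(raw))
                    slot_values.append((pos, "SEVERITY", raw.lower()))
                else:
                    val = float(raw)
                    if not (val == val and abs(val) != float("inf")):
                        raise ValueError(f"non-finite number in {sentence!r}")
                    tokens.append(NUM_ID)
                    slot_values.append((pos, "NUMBER", val))
            matched = True
            break
        if not matched:
            tokens.append(UNK_ID)
    return TokenSequence(tokens, slot_values)


def _format_number(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def detokenize(seq: TokenSequence, vocab: TemplateVocabulary) -> str:
    """Reconstruct report text; exact inverse of ``tokenize`` for UNK-free
    sequences over the same vocabulary."""
    values = {p: (t, v) for p, t, v in seq.slot_values}
    sentences: list[str] = []
    i = 0
    while i < len(seq.tokens):
        tok = seq.tokens[i]
        if tok == UNK_ID:
            sentences.append("Unk.")
            i += 1
            continue
        if tok < TEMPLATE_OFFSET:
            raise ValueError(f"dangling slot/special token {tok} at position {i}")
        entry = vocab.entry_by_id(tok)  # raises KeyError on unknown id
        fills = []
        for j, slot in enumerate(entry.slots):
            pos = i + 1 + j
            if pos >= len(seq.tokens) or pos not in values:
                raise ValueError(f"missing slot value at position {pos}")
            stype, val = values[pos]
            fills.append(_format_number(val) if stype == "NUMBER" else str(val))
        parts = entry.canonical_form.split("_")
        text = parts[0] + "".join(f + p for f, p in zip(fills, parts[1:]))
        sentences.append(text[:1].upper() + text[1:])
        i += 1 + len(entry.slots)
    return " ".join(sentences)


__all__ = [
    "TemplateEntry", "TemplateVocabulary", "TokenSequence",
    "build_vocabulary", "tokenize", "detokenize",
    "PAD_ID", "UNK_ID", "NUM_ID", "SEVERITY_OFFSET", "TEMPLATE_OFFSET",
]
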