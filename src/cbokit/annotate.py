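"""Ontology-term annotation of simulation source code.

Model code can carry its biology as plain comments: a line like

    # CBO CBO_Process CellProcess CellDeath Necrosis

states the term path from the process root down to the specific class,
and a line like ``# GO:0008219 cell death`` cross-references an external
reference ontology.  Comment characters hide the annotations from the
interpreter while leaving them in plain text, so any file indexer (or a
web search engine, for code published openly) can find a model by its
biology.  This module inserts, extracts and indexes such annotations.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ResolutionError
from .ontology import ClassHierarchy, Curie, load_core_hierarchy

__all__ = [
    "AnnotationRecord",
    "comment_prefix_for",
    "annotate_source",
    "extract_annotations",
    "build_index",
    "query",
    "save_index",
    "load_index",
]

#: comment marker by file extension (suffix -> (prefix, suffix))
_COMMENT_STYLE: dict[str, tuple[str, str]] = {
    ".py": ("#", ""),
    ".sh": ("#", ""),
    ".yaml": ("#", ""),
    ".yml": ("#", ""),
    ".xml": ("<!--", "-->"),
    ".html": ("<!--", "-->"),
    ".c": ("//", ""),
    ".h": ("//", ""),
    ".cpp": ("//", ""),
    ".java": ("//", ""),
    ".js": ("//", ""),
}

_CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_]*):(\S+)\s*(.*)$")
_TOKEN_RE = re.compile(r"[A-Za-z0-9_]+:[A-Za-z0-9_.]+|[A-Za-z0-9_]+")


@dataclass
class AnnotationRecord:
    path: str
    line: int  # 1-based line number of the CBO comment
    term_path: list[str]
    xrefs: list[Curie] = field(default_factory=list)
    comment_prefix: str = "#"
    unresolved: list[str] = field(default_factory=list)


def comment_prefix_for(path) -> tuple[str, str]:
    style = _COMMENT_STYLE.get(Path(path).suffix)
    if style is None:
        style = ("#", "")
    return style


def _resolve_path(hierarchy: ClassHierarchy, term_path: list[str]) -> list[str]:
    """Return the segments that do not resolve (empty = fully resolved)."""
    return [seg for seg in term_path if seg not in hierarchy]


# --------------------------------------------------------------------------
# annotate
# --------------------------------------------------------------------------

def annotate_source(
    path,
    insertions: list[tuple[int, object]],
    comment_prefix: str | None = None,
    hierarchy: ClassHierarchy | None = None,
) -> None:
    """Insert annotation comments above the given (1-based) lines.

    Each insertion is ``(line, term_path)`` with a list of class names, or
    ``(line, curie)`` for a reference-ontology cross-reference.  Term
    paths must resolve in the hierarchy.  Re-running with the same
    insertions is a no-op: an annotation already present immediately
    above (or at) the target line is not duplicated.
    """
    path = Path(path)
    if hierarchy is None:
        hierarchy = load_core_hierarchy()
    prefix, suffix = (
        (comment_prefix, "") if comment_prefix is not None else comment_prefix_for(path)
    )

    rendered: list[tuple[int, str]] = []
    for line_no, term in insertions:
        if isinstance(term, Curie):
            text = f"{prefix} {term}"
        elif isinstance(term, str) and _CURIE_RE.match(term):
            text = f"{prefix} {term}"
        else:
            term_path = list(term)
            bad = _resolve_path(hierarchy, term_path)
            if bad:
                raise ResolutionError(f"unresolvable term(s) {bad} in {term_path}")
            text = f"{prefix} CBO " + " ".join(term_path)
        if suffix:
            text += f" {suffix}"
        rendered.append((line_no, text))

    lines = path.read_text(encoding="utf-8").splitlines()
    # insert bottom-up so earlier line numbers stay valid
    for line_no, text in sorted(rendered, key=lambda t: -t[0]):
        idx = min(max(line_no - 1, 0), len(lines))
        already = (idx < len(lines) and lines[idx].strip() == text) or (
            idx > 0 and lines[idx - 1].strip() == text
        )
        if already:
            continue
        indent = ""
        if idx < len(lines):
            m = re.match(r"\s*", lines[idx])
            indent = m.group(0) if m else ""
        lines.insert(idx, indent + text)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# extract
# --------------------------------------------------------------------------

def extract_annotations(
    path, hierarchy: ClassHierarchy | None = None
) -> list[AnnotationRecord]:
    """Find all annotation comments in a file, in file order.

    ``<prefix> CBO <path...>`` lines become records; a CURIE comment on
    the line immediately after a record attaches to it as a
    cross-reference, otherwise it forms its own record.  Unresolved path
    segments are reported on the record, never fatal.
    """
    path = Path(path)
    if hierarchy is None:
        hierarchy = load_core_hierarchy()
    prefix, suffix = comment_prefix_for(path)

    records: list[AnnotationRecord] = []
    last: AnnotationRecord | None = None
    last_line = -10
    for i, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        stripped = raw.strip()
        if not stripped.startswith(prefix):
            continue
        body = stripped[len(prefix):].strip()
        if suffix and body.endswith(suffix):
            body = body[: -len(suffix)].strip()
        if body.startswith("CBO "):
            term_path = body.split()[1:]
            rec = AnnotationRecord(
                path=str(path),
                line=i,
                term_path=term_path,
                comment_prefix=prefix,
                unresolved=_resolve_path(hierarchy, term_path),
            )
            records.append(rec)
            last, last_line = rec, i
            continue
        m = _CURIE_RE.match(body)
        if m and m.group(1) not in ("http", "https"):
            curie = Curie(m.group(1), m.group(2))
            if last is not None and i == last_line + 1:
                last.xrefs.append(curie)
                last_line = i
            else:
                records.append(
                    AnnotationRecord(
                        path=str(path), line=i, term_path=[str(curie)],
                        xrefs=[curie], comment_prefix=prefix,
                    )
                )
    return records


# --------------------------------------------------------------------------
# index / query
# --------------------------------------------------------------------------

def build_index(directory, extensions=None) -> dict[str, dict[str, int]]:
    """Map every token of the scanned files to per-file match counts.

    All word tokens and CURIE tokens of each file are indexed (the whole
    text, as a web indexer would see it), so queries can mix ontology
    class names with free comment words.
    """
    directory = Path(directory)
    exts = set(extensions) if extensions else set(_COMMENT_STYLE)
    index: dict[str, dict[str, int]] = {}
    for p in sorted(directory.rglob("*")):
        if not p.is_file() or p.suffix not in exts:
            continue
        try:
            text = p.read_text(encoding="utf-8")
        except UnicodeDecodeError:
            continue
        rel = str(p.relative_to(directory))
        for tok in _TOKEN_RE.findall(text):
            index.setdefault(tok, {})[rel] = index.get(tok, {}).get(rel, 0) + 1
    return index


def query(index: dict[str, dict[str, int]], terms) -> list[str]:
    """Files containing ALL query terms, ranked by total match count."""
    terms = list(terms)
    if not terms:
        return []
    per_term = [index.get(t, {}) for t in terms]
    common = set(per_term[0])
    for d in per_term[1:]:
        common &= set(d)
    scored = sorted(
        common, key=lambda f: (-sum(d[f] for d in per_term), f)
    )
    return scored


def save_index(index, path) -> None:
    Path(path).write_text(json.dumps(index, indent=0, sort_keys=True), encoding="utf-8")


def load_index(path) -> dict[str, dict[str, int]]:
    return json.loads(Path(path).read_text(encoding="utf-8"))
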