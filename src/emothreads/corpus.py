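"""Data model and IO for valence-labelled discussion threads.

A corpus is a collection of discussion threads; each thread is an ordered
chain of posts carrying a ternary emotional valence: -1 (negative),
0 (neutral) or +1 (positive).  Reply trees are flattened to chronological
chains before any sequence analysis; parent links are kept as metadata only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VALENCES",
    "Post",
    "Thread",
    "Corpus",
    "CorpusSummary",
    "FormatSpec",
    "read_corpus",
    "write_corpus",
    "flatten_thread",
    "summarize",
    "shuffle_corpus",
]

#: Canonical ascending order of the three valence classes.
VALENCES = (-1, 0, 1)

_VALID_VALENCES = frozenset(VALENCES)


@dataclass(frozen=True)
class Post:
    """A single comment in a discussion thread."""

    post_id: str
    thread_id: str
    order_key: float | int | str
    valence: int
    parent_post_id: str | None = None

    def __post_init__(self) -> None:
        if self.valence not in _VALID_VALENCES:
            raise ValueError(
                f"post {self.post_id!r}: valence must be -1, 0 or +1, got {self.valence!r}"
            )


class Thread:
    """An ordered chain of posts sharing one thread_id.

    The valence sequence is stored as a compact int8 array; post ids,
    order keys and parent links are optional metadata carried along for
    provenance but never consulted by the sequence statistics.
    """

    __slots__ = ("thread_id", "valences", "post_ids", "order_keys", "parents")

    def __init__(
        self,
        thread_id: str,
        valences: Sequence[int] | np.ndarray,
        post_ids: Sequence[str] | None = None,
        order_keys: Sequence | None = None,
        parents: Mapping[str, str | None] | None = None,
    ) -> None:
        v = np.asarray(valences, dtype=np.int8)
        if v.ndim != 1 or v.size == 0:
            raise ValueError(f"thread {thread_id!r}: needs a non-empty 1-d valence sequence")
        bad = ~np.isin(v, VALENCES)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"thread {thread_id!r}: invalid valence {v[i]} at position {i}"
            )
        if post_ids is not None and len(post_ids) != v.size:
            raise ValueError(f"thread {thread_id!r}: post_ids length mismatch")
        self.thread_id = thread_id
        self.valences = v
        self.post_ids = list(post_ids) if post_ids is not None else None
        self.order_keys = list(order_keys) if order_keys is not None else None
        self.parents = dict(parents) if parents is not None else None

    def __len__(self) -> int:
        return int(self.valences.size)

    @property
    def length(self) -> int:
        return len(self)

    def __repr__(self) -> str:
        return f"Thread({self.thread_id!r}, L={len(self)})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Thread)
            and self.thread_id == other.thread_id
            and np.array_equal(self.valences, other.valences)
        )


class Corpus:
    """A collection of threads with unique thread ids."""

    def __init__(self, threads: Iterable[Thread], provenance: str = "") -> None:
        self.threads: list[Thread] = list(threads)
        seen: set[str] = set()
        for t in self.threads:
            if t.thread_id in seen:
                raise ValueError(f"duplicate thread_id {t.thread_id!r}")
            seen.add(t.thread_id)
        self.provenance = provenance
        self._flat: tuple[np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.threads)

    def __iter__(self) -> Iterator[Thread]:
        return iter(self.threads)

    @property
    def n_threads(self) -> int:
        return len(self.threads)

    @property
    def n_comments(self) -> int:
        return sum(len(t) for t in self.threads)

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated valences and thread start offsets.

        Returns ``(values, offsets)`` where ``values`` is the int8
        concatenation of all thread valence sequences and ``offsets`` has
        ``n_threads + 1`` entries delimiting each thread
        (``values[offsets[j]:offsets[j+1]]`` is thread ``j``).
        """
        if self._flat is None:
            if not self.threads:
                raise ValueError("empty corpus")
            values = np.concatenate([t.valences for t in self.threads])
            lengths = np.fromiter(
                (len(t) for t in self.threads), dtype=np.int64, count=len(self.threads)
            )
            offsets = np.concatenate([[0], np.cumsum(lengths)])
            self._flat = (values, offsets)
        return self._flat

    def __repr__(self) -> str:
        return f"Corpus(n_threads={self.n_threads}, n_comments={self.n_comments})"


@dataclass(frozen=True)
class CorpusSummary:
    """Pooled corpus statistics: counts, mean valence, class frequencies.

    ``p_plus``/``p_minus``/``p_zero`` are the fractions of posts with
    valence +1/-1/0 over all posts pooled across threads.
    """

    n_comments: int
    n_threads: int
    mean_valence: float
    p_plus: float
    p_minus: float
    p_zero: float
    n_users: int | None = None

    def p(self, valence: int) -> float:
        """Frequency of a given valence class."""
        return {1: self.p_plus, -1: self.p_minus, 0: self.p_zero}[valence]

    def to_dict(self) -> dict:
        return {
            "n_comments": self.n_comments,
            "n_threads": self.n_threads,
            "n_users": self.n_users,
            "mean_valence": self.mean_valence,
            "p_plus": self.p_plus,
            "p_minus": self.p_minus,
            "p_zero": self.p_zero,
        }


# ---------------------------------------------------------------------------
# Reading and writing

#: Default column mapping for on-disk tables.
DEFAULT_COLUMNS = {
    "thread_id": "thread_id",
    "post_id": "post_id",
    "order": "order",
    "parent": "parent_post_id",
    "valence": "valence",
}

#: Accepted string spellings of the three valence classes.
DEFAULT_VALENCE_MAP = {
    "-1": -1, "0": 0, "1": 1, "+1": 1,
    "neg": -1, "neu": 0, "pos": 1,
    "negative": -1, "neutral": 0, "positive": 1,
}


@dataclass
class FormatSpec:
    """Column/key mapping for corpus files.

    ``columns`` maps the logical fields (thread_id, post_id, order, parent,
    valence) to the names used in the file; ``valence_map`` maps raw cell
    values to {-1, 0, +1}.  Integers -1/0/+1 are always accepted.
    """

    columns: dict = field(default_factory=lambda: dict(DEFAULT_COLUMNS))
    valence_map: dict = field(default_factory=lambda: dict(DEFAULT_VALENCE_MAP))

    @classmethod
    def from_mapping(cls, mapping: Mapping | None) -> "FormatSpec":
        if mapping is None:
            return cls()
        cols = dict(DEFAULT_COLUMNS)
        vmap = dict(DEFAULT_VALENCE_MAP)
        for key, val in mapping.items():
            if key == "valence_map":
                vmap.update({str(k): v for k, v in val.items()})
            elif key in cols:
                cols[key] = val
            else:
                raise KeyError(f"unknown format_spec field {key!r}")
        return cls(cols, vmap)


def _parse_valence(raw, spec: FormatSpec, row_label) -> int:
    if isinstance(raw, (int, np.integer)) and int(raw) in _VALID_VALENCES:
        return int(raw)
    if isinstance(raw, (float, np.floating)) and raw in (-1.0, 0.0, 1.0):
        return int(raw)
    key = str(raw).strip().lower()
    if key in spec.valence_map:
        return int(spec.valence_map[key])
    raise ValueError(f"row {row_label}: cannot parse valence {raw!r} (expected -1, 0 or +1)")


def read_corpus(
    path: str | Path,
    format_spec: FormatSpec | Mapping | None = None,
    fmt: str | None = None,
) -> Corpus:
    """Read a corpus from a CSV (header required) or JSON-lines file.

    Posts are grouped by thread id and each thread is flattened to its
    chronological chain via :func:`flatten_thread`.  The file format is
    inferred from the suffix unless ``fmt`` ("csv" or "jsonl") is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spec = format_spec if isinstance(format_spec, FormatSpec) else FormatSpec.from_mapping(format_spec)
    if fmt is None:
        fmt = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson", ".json"} else "csv"
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif fmt == "jsonl":
        df = pd.read_json(path, lines=True, dtype=str)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if df.empty:
        raise ValueError(f"{path}: no posts found")

    cols = spec.columns
    for logical in ("thread_id", "post_id", "order", "valence"):
        if cols[logical] not in df.columns:
            raise ValueError(f"{path}: missing required column {cols[logical]!r}")
    has_parent = cols["parent"] in df.columns

    threads = []
    for thread_id, group in df.groupby(cols["thread_id"], sort=True):
        if str(thread_id).strip() == "":
            raise ValueError(f"{path}: post(s) with missing thread_id")
        posts = []
        for row_label, row in group.iterrows():
            parent = row[cols["parent"]] if has_parent else None
            if parent is not None and str(parent).strip() == "":
                parent = None
            posts.append(
                Post(
                    post_id=str(row[cols["post_id"]]),
                    thread_id=str(thread_id),
                    order_key=_coerce_order(row[cols["order"]]),
                    valence=_parse_valence(row[cols["valence"]], spec, row_label),
                    parent_post_id=parent,
                )
            )
        threads.append(flatten_thread(posts))
    return Corpus(threads, provenance=str(path))


def _coerce_order(raw):
    try:
        f = float(raw)
    except (TypeError, ValueError):
        return str(raw)
    return int(f) if f == int(f) else f


def write_corpus(corpus: Corpus, path: str | Path, fmt: str | None = None) -> None:
    """Write a corpus as CSV or JSON-lines with the default column names."""
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson", ".json"} else "csv"
    records = []
    for t in corpus:
        ids = t.post_ids or [f"{t.thread_id}:{i}" for i in range(len(t))]
        keys = t.order_keys or list(range(len(t)))
        parents = t.parents or {}
        for i, (pid, key, v) in enumerate(zip(ids, keys, t.valences)):
            records.append(
                {
                    "thread_id": t.thread_id,
                    "post_id": pid,
                    "order": key,
                    "parent_post_id": parents.get(pid),
                    "valence": int(v),
                }
            )
    df = pd.DataFrame.from_records(records)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "jsonl":
        df.to_json(path, orient="records", lines=True)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Thread assembly and summaries

def flatten_thread(posts: Sequence[Post]) -> Thread:
    """Order a set of posts chronologically, ignoring the reply tree.

    Discussions with a tree structure are converted to a single chain by
    sorting on the order key (timestamp or ordinal); parent links survive
    only as metadata.  Ties in order key are broken by post_id so the chain
    is deterministic.
    """
    if not posts:
        raise ValueError("cannot flatten an empty set of posts")
    thread_ids = {p.thread_id for p in posts}
    if len(thread_ids) != 1:
        raise ValueError(f"posts span multiple thread_ids: {sorted(thread_ids)!r}")
    keyed = sorted(posts, key=lambda p: (p.order_key, p.post_id))
    for a, b in zip(keyed, keyed[1:]):
        if a.order_key == b.order_key and a.post_id == b.post_id:
            raise ValueError(
                f"thread {a.thread_id!r}: duplicate (order_key, post_id) = "
                f"({a.order_key!r}, {a.post_id!r})"
            )
    return Thread(
        thread_id=posts[0].thread_id,
        valences=[p.valence for p in keyed],
        post_ids=[p.post_id for p in keyed],
        order_keys=[p.order_key for p in keyed],
        parents={p.post_id: p.parent_post_id for p in keyed},
    )


def summarize(corpus: Corpus, n_users: int | None = None) -> CorpusSummary:
    """Pooled class frequencies and mean valence over all posts.

    Each ``p_e`` is the number of posts with valence ``e`` divided by the
    total number of posts, pooled across threads.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    values, _ = corpus.flat()
    n = values.size
    counts = {e: int(np.count_nonzero(values == e)) for e in VALENCES}
    return CorpusSummary(
        n_comments=n,
        n_threads=corpus.n_threads,
        n_users=n_users,
        mean_valence=float(values.mean()),
        p_plus=counts[1] / n,
        p_minus=counts[-1] / n,
        p_zero=counts[0] / n,
    )


def shuffle_corpus(corpus: Corpus, seed: int) -> Corpus:
    """Within-thread surrogate: permute each thread's valences uniformly.

    Thread membership, thread lengths and per-thread valence counts are
    preserved exactly, so all pooled marginals are unchanged; only the
    within-thread ordering (and hence any clustering) is destroyed.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for t in corpus:
        out.append(Thread(t.thread_id, rng.permutation(t.valences)))
    return Corpus(out, provenance=f"{corpus.provenance} [shuffled seed={seed}]")


def summary_to_json(summary: CorpusSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2))
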