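"""End-to-end inference: enumerate, score, rank, cache and export.

The output CSV follows the screening-server conventions: named
``[sequence]-[modification].csv`` with a header row ``chemically
modified sequence,score``, rows in descending score order, and the
modified-sequence column written in the bracket-token notation with
``*`` marking every PS linkage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

from .chemistry import FragmentLibrary
from .egt import RankerModel, score_batch
from .errors import NotationError
from .notation import pattern_to_notation
from .patterns import ModificationPattern, enumerate_full_patterns, enumerate_gapmer_wing_patterns
from .sequences import AsoSequence
from .training import FeatureCache

logger = logging.getLogger("asoforge.ranking")

CSV_HEADER = "chemically modified sequence,score"


@dataclass(frozen=True)
class RankedResult:
    """One row of the ranked output table."""

    notation: str
    score: float


class QueryCache:
    """Persistent JSON store of full ranked result lists.

    Keys hash the normalized sequence, modification type, enumeration
    mode *and the model's version_id*, so results are invalidated
    automatically when the model is retrained. A cache hit reproduces
    the original result list exactly (float values round-trip through
    JSON's shortest-repr encoding).
    """

    def __init__(self, path):
        self.path = Path(path)
        self._data: dict[str, list[list]] = {}
        if self.path.exists():
            self._data = json.loads(self.path.read_text(encoding="utf-8"))

    @staticmethod
    def key(seq: AsoSequence, chem: str, mode: str, version_id: str) -> str:
        raw = f"{seq}|{chem}|{mode}|{version_id}"
        return hashlib.sha256(raw.encode()).hexdigest()[:32]

    def get(self, key: str) -> list[RankedResult] | None:
        rows = self._data.get(key)
        if rows is None:
            return None
        return [RankedResult(notation=n, score=s) for n, s in rows]

    def put(self, key: str, results: list[RankedResult]) -> None:
        self._data[key] = [[r.notation, r.score] for r in results]
        self.path.write_text(
            json.dumps(self._data, ensure_ascii=False), encoding="utf-8"
        )


def rank_patterns(
    model: RankerModel,
    seq: AsoSequence,
    chem: str,
    enumeration_mode: str = "gapmer",
    top_k: int = 10,
    cache: QueryCache | None = None,
    library: FragmentLibrary | None = None,
    wing_len: int = 5,
    variable_wing_positions: frozenset[int] = frozenset({2, 3, 4, 5}),
    enumeration_cap: int | None = None,
    batch_size: int = 8,
    feature_cache: FeatureCache | None = None,
) -> list[RankedResult]:
    """Score every enumerated pattern of a sequence and rank descending.

    ``enumeration_mode`` is ``"gapmer"`` (wing enumeration) or
    ``"full"`` (all ``2**l`` single-chemistry patterns, subject to the
    enumeration cap). Ties are broken by ascending notation string.
    The full sorted list is returned; the top-``top_k`` summary is a
    prefix of it (see :func:`summarize`). With a :class:`QueryCache`,
    a repeated identical query is served from the store without
    recomputation.
    """
    if enumeration_mode not in ("full", "gapmer"):
        raise ValueError(f"unknown enumeration mode {enumeration_mode!r}")
    cache_key = None
    if cache is not None:
        cache_key = QueryCache.key(seq, chem, enumeration_mode, model.version_id)
        hit = cache.get(cache_key)
        if hit is not None:
            logger.info("cache hit for %s-%s (%d results)", seq, chem, len(hit))
            return hit

    t0 = time.time()
    if enumeration_mode == "gapmer":
        patterns = enumerate_gapmer_wing_patterns(
            seq, chem, wing_len=wing_len,
            variable_wing_positions=variable_wing_positions,
        )
    else:
        from .patterns import DEFAULT_ENUMERATION_CAP

        cap = DEFAULT_ENUMERATION_CAP if enumeration_cap is None else enumeration_cap
        patterns = list(enumerate_full_patterns(seq, chem, cap=cap))
    logger.info("enumerated %d patterns in %.2fs", len(patterns), time.time() - t0)

    t0 = time.time()
    feature_cache = feature_cache or FeatureCache(library)
    feats = [feature_cache(seq, p) for p in patterns]
    logger.info("assembled and featurized in %.2fs", time.time() - t0)

    t0 = time.time()
    scores: list[float] = []
    for start in range(0, len(feats), batch_size):
        scores.extend(score_batch(model, feats[start : start + batch_size]))
    logger.info("scored in %.2fs", time.time() - t0)

    rows = [
        RankedResult(notation=pattern_to_notation(seq, p), score=float(s))
        for p, s in zip(patterns, scores)
    ]
    rows.sort(key=lambda r: (-r.score, r.notation))
    if cache is not None and cache_key is not None:
        cache.put(cache_key, rows)
    return rows


def summarize(results: list[RankedResult], top_k: int = 10) -> list[RankedResult]:
    """The top-``top_k`` rows of a ranked result list."""
    return results[:top_k]


def write_results_csv(
    seq: AsoSequence, chem: str, results: list[RankedResult], directory
) -> Path:
    """Write the ranked results as ``[sequence]-[modification].csv``.

    Scores are printed with 6 decimal places so reruns of an identical
    model produce byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{seq}-{chem}.csv"
    lines = [CSV_HEADER]
    lines += [f"{r.notation},{r.score:.6f}" for r in results]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_results_csv(path) -> list[RankedResult]:
    """Read back a results CSV written by :func:`write_results_csv`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != CSV_HEADER:
        raise NotationError(f"unexpected CSV header in {path}")
    out = []
    for line in lines[1:]:
        notation, score = line.rsplit(",", 1)
        out.append(RankedResult(notation=notation, score=float(score)))
    return out
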