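"""End-to-end analysis pipeline: corpus in, tidy CSV tables + manifest out.

One :func:`run_pipeline` call takes a corpus (from disk or from a
generator spec), runs the requested analysis stages per valence class, and
writes every result as tidy CSV plus a JSON manifest recording the seed,
the config hash and all output files.  Reruns with the same config and
seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import clusters as cl
from . import lifespan as ls
from . import preferential as pf
from .corpus import Corpus, read_corpus, shuffle_corpus, summarize
from .generate import GeneratorSpec, generate

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("emothreads")

ANALYSES = ("clusters", "preferential", "lifespan", "nulls")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (with optional ``format_spec``) or
    ``generator`` must be given.
    """

    out_dir: str | Path
    input_path: str | Path | None = None
    format_spec: Mapping | None = None
    generator: GeneratorSpec | Mapping | None = None
    analyses: Sequence[str] = ANALYSES
    n_shuffles: int = 1
    seed: int = 0
    n_max: int = 10
    fit_range: tuple[int, int] = (1, 10)
    target_lengths: Sequence[int] = (20, 40, 60, 80)
    window: int = 10

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path or generator must be set")
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        if self.n_shuffles < 0:
            raise ValueError("n_shuffles must be >= 0")
        if isinstance(self.generator, Mapping):
            self.generator = GeneratorSpec(**self.generator)

    def digest(self) -> str:
        payload = {
            "input_path": str(self.input_path) if self.input_path else None,
            "format_spec": dict(self.format_spec) if self.format_spec else None,
            "generator": None if self.generator is None else {
                k: (list(v) if isinstance(v, (tuple, list, np.ndarray)) else v)
                for k, v in vars(self.generator).items()
            },
            "analyses": list(self.analyses),
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
            "n_max": self.n_max,
            "fit_range": list(self.fit_range),
            "target_lengths": list(self.target_lengths),
            "window": self.window,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load(config: PipelineConfig) -> Corpus:
    if config.input_path is not None:
        return read_corpus(config.input_path, config.format_spec)
    spec = config.generator
    if spec.seed != config.seed:
        spec = GeneratorSpec(**{**vars(spec), "seed": config.seed})
    return generate(spec)


def _present_valences(corpus: Corpus):
    values, _ = corpus.flat()
    return [e for e in (1, -1, 0) if np.any(values == e)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and write the report bundle.

    Returns the manifest dict (also written to ``manifest.json``).  Any
    stage error propagates after being logged; partial outputs may remain
    on disk but are not listed in a manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        outputs.append(name)
        log.info("wrote %s (%d rows)", path, len(df))

    try:
        corpus = _load(config)
        valences = _present_valences(corpus)
        summ = summarize(corpus)
        emit(pd.DataFrame([summ.to_dict()]), "summary.csv")

        curves: dict[int, pf.ConditionalCurve] = {}
        fits: dict[int, pf.PreferentialFit] = {}
        if "preferential" in config.analyses or "clusters" in config.analyses:
            for e in valences:
                try:
                    curves[e] = pf.conditional_extension_curve(corpus, e, config.n_max)
                    fits[e] = pf.fit_alpha(curves[e], config.fit_range)
                except ValueError as err:
                    warnings.warn(f"valence {e:+d}: no preferential fit ({err})")

        if "clusters" in config.analyses:
            frames = []
            for e in valences:
                dist = cl.cluster_length_distribution(corpus, e)
                p_e = summ.p(e)
                models = {"iid_ccdf": lambda n, p=p_e: cl.iid_cluster_ccdf(p, n)}
                if e in fits:
                    f = fits[e]
                    models["preferential_ccdf"] = (
                        lambda n, f=f: cl.preferential_cluster_ccdf(f.p1, f.alpha, n)
                    )
                df = dist.to_frame()
                for col, fn in models.items():
                    df[col] = [fn(int(n)) for n in df["n"]]
                frames.append(df)
            emit(pd.concat(frames, ignore_index=True), "cluster_distributions.csv")

        if "preferential" in config.analyses:
            if curves:
                emit(
                    pd.concat([c.to_frame() for c in curves.values()], ignore_index=True),
                    "conditional_curves.csv",
                )
            if fits:
                emit(
                    pd.DataFrame(
                        [
                            {
                                "valence": f.valence,
                                "p_e": summ.p(f.valence),
                                "p1": f.p1,
                                "alpha": f.alpha,
                                "alpha_stderr": f.alpha_stderr,
                                "r_squared": f.r_squared,
                                "n_points": f.n_points,
                            }
                            for f in fits.values()
                        ]
                    ),
                    "alpha_fits.csv",
                )

        if "nulls" in config.analyses and config.n_shuffles > 0:
            rows = []
            for s in range(config.n_shuffles):
                surrogate = shuffle_corpus(corpus, seed=config.seed + 1 + s)
                for e in valences:
                    curve = pf.conditional_extension_curve(surrogate, e, config.n_max)
                    for n in curve.ns():
                        pt = curve.points[n]
                        rows.append(
                            {
                                "shuffle": s,
                                "valence": e,
                                "n": n,
                                "p_hat": pt.p_hat,
                                "denominator": pt.denominator,
                                "p_e": summ.p(e),
                            }
                        )
            emit(pd.DataFrame(rows), "shuffle_null_curves.csv")

        if "lifespan" in config.analyses:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                profiles = ls.grouped_lifespan_profiles(
                    corpus, config.target_lengths, config.window
                )
            if profiles:
                emit(
                    pd.concat([p.to_frame() for p in profiles], ignore_index=True),
                    "lifespan_profiles.csv",
                )
            eligible = [t for t in corpus if len(t) >= 2 * config.window]
            if eligible:
                emit(
                    pd.DataFrame(
                        {
                            "thread_id": [t.thread_id for t in eligible],
                            "length": [len(t) for t in eligible],
                            "fuel_delta": [ls.fuel_delta(t, config.window) for t in eligible],
                        }
                    ),
                    "fuel_deltas.csv",
                )
            try:
                bins = ls.length_vs_initial_emotion(corpus, config.window)
                emit(
                    pd.DataFrame([vars(b) for b in bins]),
                    "length_vs_initial_emotion.csv",
                )
            except ValueError as err:
                warnings.warn(f"length-vs-initial-emotion skipped: {err}")
    except Exception:
        log.exception("pipeline stage failed; halting")
        raise

    manifest = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "provenance": corpus.provenance,
        "n_threads": corpus.n_threads,
        "n_comments": corpus.n_comments,
        "analyses": list(config.analyses),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
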