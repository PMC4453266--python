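"""Orchestration: build-space -> represent -> score -> compare -> rank.

One configured run reads a background corpus and a labeled corpus, builds
the semantic space, scores every labeled document on the 13 traits,
compares the groups, ranks the documents with the three models plus the
mean-of-ranks ensemble, and writes everything into a run directory as
auditable CSV/JSON/text artifacts.  Re-running the same config reproduces
all non-timestamp content; artifacts that already exist (the space) are
reused so downstream stages can be re-run cheaply.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corpus_io import Corpus, load_corpus, log, write_scores
from .group_stats import compare_groups
from .prioritization import (
    DEFAULT_MODELS,
    ModelSpec,
    random_baseline_steps,
    rank_documents,
    screening_report,
)
from .representation import DictionaryTagger, represent_corpus
from .semantic_space import SpaceConfig, build_space, load_space, save_space
from .trait_scoring import builtin_lexicon, load_lexicon, score_corpus

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All inputs of one end-to-end run."""

    background_dir: str
    labeled_dir: str
    labels_csv: str
    out_dir: str
    pos_dictionary_json: str
    space: SpaceConfig = field(default_factory=SpaceConfig)
    scoring_mode: str = "centroid"
    model_kinds: tuple[str, ...] = ("logistic", "tree", "knn")
    ranking_mode: str = "insample"
    n_permutations: int = 10000
    seed: int = 13
    k_top: int = 10
    lexicon_csv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        space_keys = {"window", "weighting", "svd_dim", "min_count"}
        space = SpaceConfig(
            **{k: raw.pop(k) for k in list(raw) if k in space_keys},
            seed=int(raw.get("seed", 13)),
        )
        if "model_kinds" in raw:
            raw["model_kinds"] = tuple(raw["model_kinds"])
        return cls(space=space, **raw)


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage, returning the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = {
        name: _stage_seed(config.seed, name) for name in ("space", "mwu", "rank")
    }

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # Stage 1: semantic space (reused if already on disk).
    space_prefix = out / "space"
    try:
        if all(
            Path(f"{space_prefix}{ext}").exists()
            for ext in (".vocab.txt", ".vectors.txt", ".json")
        ):
            log("space artifacts found; skipping rebuild")
            space = load_space(space_prefix)
        else:
            background = load_corpus(config.background_dir)
            space_cfg = SpaceConfig(
                window=config.space.window,
                weighting=config.space.weighting,
                svd_dim=config.space.svd_dim,
                min_count=config.space.min_count,
                seed=stage_seeds["space"],
            )
            space = build_space(background, space_cfg)
            save_space(space, space_prefix)
            log(f"built semantic space: {len(space.vocabulary)} words")
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        fail("space", exc)

    # Stage 2: representations.
    try:
        labeled = load_corpus(config.labeled_dir, config.labels_csv)
        pos_dict = json.loads(
            Path(config.pos_dictionary_json).read_text(encoding="utf-8")
        )
        tagger = DictionaryTagger(pos_dict)
        reps = represent_corpus(labeled, tagger, k=config.k_top)
        reps_path = out / "representations.json"
        reps_path.write_text(
            json.dumps(
                {
                    r.doc_id: {
                        "nouns": [list(p) for p in r.nouns],
                        "verbs": [list(p) for p in r.verbs],
                        "adjectives": [list(p) for p in r.adjectives],
                    }
                    for r in reps
                },
                indent=1,
                sort_keys=True,
            ),
            encoding="utf-8",
        )
        log(f"represented {len(reps)} documents")
    except Exception as exc:  # noqa: BLE001
        fail("represent", exc)

    # Stage 3: trait scores.
    try:
        lexicon = (
            load_lexicon(config.lexicon_csv) if config.lexicon_csv else builtin_lexicon()
        )
        matrix = score_corpus(
            space, reps, lexicon, mode=config.scoring_mode, labels=labeled.labels
        )
        write_scores(matrix, out / "scores.csv")
        (out / "oov_report.json").write_text(
            json.dumps(
                {
                    "seed_oov_per_trait": {
                        t: int(matrix.seed_oov[t].iloc[0]) for t in matrix.trait_names
                    },
                    "rep_oov_per_doc": {
                        d: int(v) for d, v in matrix.rep_oov.items() if v
                    },
                },
                indent=1,
                sort_keys=True,
            ),
            encoding="utf-8",
        )
        log("scored corpus on 13 traits" if len(lexicon) == 13 else "scored corpus")
    except Exception as exc:  # noqa: BLE001
        fail("score", exc)

    # Stage 4: group comparison.
    try:
        mwu = compare_groups(
            matrix,
            n_permutations=config.n_permutations,
            seed=stage_seeds["mwu"],
        )
        mwu.to_csv(out / "mwu.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        fail("compare", exc)

    # Stage 5: ranking and screening.
    try:
        specs = tuple(ModelSpec(kind=k) for k in config.model_kinds) or DEFAULT_MODELS
        results = rank_documents(
            matrix, specs=specs, mode=config.ranking_mode, seed=stage_seeds["rank"]
        )
        rows = []
        for r in results:
            for doc_id in matrix.doc_ids:
                rows.append(
                    {
                        "model": r.model_name,
                        "doc_id": doc_id,
                        "probability": (
                            float(r.probabilities[doc_id])
                            if r.probabilities is not None
                            else np.nan
                        ),
                        "rank": int(r.ranks[doc_id]),
                        "label": labeled[doc_id].label,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "ranking.csv", index=False)
        n_docs = len(matrix.doc_ids)
        n_pos = int((labeled.labels == "positive").sum())
        report = screening_report(results, n_docs=n_docs, n_positive=n_pos)
        report.to_csv(out / "ranking_summary.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        fail("rank", exc)

    # Manifest + human-readable summary.
    manifest = {
        "traitspace_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": {
            **{
                k: v
                for k, v in asdict(config).items()
                if k != "space"
            },
            "space": asdict(config.space),
        },
        "stage_seeds": stage_seeds,
        "n_documents": n_docs,
        "n_positive": n_pos,
        "vocabulary_size": len(space.vocabulary),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )

    lines = [
        f"traitspace run (seed {config.seed})",
        f"documents: {n_docs} ({n_pos} positive), vocabulary: {len(space.vocabulary)}",
        "",
        "group comparison (Mann-Whitney U, Monte-Carlo p):",
    ]
    for _, row in mwu.iterrows():
        lines.append(
            f"  {row['trait']:<12} U={row['U']:<10g} p_mc={row['p_mc']:.4g} "
            f"(n1={row['n1']}, n2={row['n2']})"
        )
    lines += ["", "screening (steps to identify all positives):"]
    baseline = random_baseline_steps(n_pos, n_docs)
    for _, row in report.iterrows():
        lines.append(
            f"  {row['model']:<5} steps={int(row['steps']):<6} "
            f"fraction={row['fraction_pct']:.2f}% "
            f"(~{int(row['fraction_rounded_pct'])}%)"
        )
    lines.append(f"  random-ranking baseline: {baseline:.1f} steps")
    (out / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    log(f"run complete: {out}")
    return out
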