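"""End-to-end pipeline: clean → vectorize → split → resample → select → train → evaluate.

A single global seed deterministically derives one seed per stage (by hashing
the stage name), so the whole run — and any stage rerun in isolation — is
reproducible. Every intermediate artifact (cleaned corpus, vocabulary,
selected subset, search trace, network weights, RMSE history, confusion
matrix, report) is persisted as plain text in the output directory, and
identical config + seed produces byte-identical report files.

Configuration is a YAML mapping; :func:`validate_config` checks every
invariant, rejects unknown keys, and fills documented defaults.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

from . import bpnn as bpnn_mod
from .bpnn import BPNNConfig, save_model
from .corpus import Corpus, read_corpus, write_corpus
from .evaluate import EvalReport, confusion, metrics_from_confusion
from .iwd import FeatureSubset, IWDParams, run_iwd
from .preprocess import CleanConfig, clean_corpus
from .synth import SynthSpec, default_table1_spec
from .vectorize import (
    build_vocabulary,
    resample,
    stratified_split,
    tfidf_weight,
    vectorize_counts,
)
from . import synth as synth_mod

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "PipelineError",
    "validate_config",
    "run_pipeline",
    "derive_seed",
]

log = logging.getLogger("emodrop")


class ConfigError(ValueError):
    """Invalid pipeline configuration; ``errors`` lists all violations."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def derive_seed(global_seed: int, stage: str) -> int:
    """Stage seed derived from the global seed by hashing the stage name."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode("utf-8"))) % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Fully resolved pipeline configuration."""

    seed: int = 0
    # input: either a corpus file ...
    input_path: str | None = None
    input_format: str = "delimited"
    text_field: str = "text"
    label_field: str = "label"
    # ... or a synthetic-corpus spec
    synth: SynthSpec | None = None
    clean: CleanConfig = field(default_factory=CleanConfig)
    ngram_orders: tuple[int, ...] = (1,)
    weighting: str = "counts"  # counts | tfidf
    resample_mode: str = "oversample"  # oversample | undersample | none
    test_fraction: float = 0.2
    drop_minority_class: bool = False
    feature_selection: str = "iwd"  # iwd | none
    iwd: IWDParams = field(default_factory=IWDParams)
    bpnn: BPNNConfig = field(default_factory=BPNNConfig)
    output_dir: str = "emodrop_out"


_TOP_KEYS = {
    "seed",
    "input",
    "synth",
    "clean",
    "vectorize",
    "split",
    "resample",
    "drop_minority_class",
    "feature_selection",
    "bpnn",
    "output_dir",
}
_INPUT_KEYS = {"path", "format", "text_field", "label_field"}
_SYNTH_KEYS = {"scale"} | {f.name for f in dataclasses.fields(SynthSpec)}
_CLEAN_KEYS = {
    "stopword_file",
    "common_df_threshold",
    "rare_min_count",
    "enable_lowercase",
    "enable_punctuation",
    "enable_stopwords",
    "enable_common",
    "enable_rare",
}
_VEC_KEYS = {"ngram_orders", "weighting"}
_SPLIT_KEYS = {"test_fraction"}
_FS_KEYS = {"method"} | {f.name for f in dataclasses.fields(IWDParams)}
_BPNN_KEYS = {f.name for f in dataclasses.fields(BPNNConfig)}


def _check_keys(section: dict, allowed: set[str], where: str, errors: list[str]) -> None:
    for key in section:
        if key not in allowed:
            errors.append(f"{where}{key}: unknown key")


def validate_config(raw: str | dict) -> PipelineConfig:
    """Parse and validate a YAML/dict configuration.

    Every violation is collected (with its field path) before raising
    :class:`ConfigError`; defaults are filled for absent keys.
    """
    if isinstance(raw, str):
        try:
            data = yaml.safe_load(raw)
        except yaml.YAMLError as exc:
            raise ConfigError([f"config is not valid YAML: {exc}"]) from exc
    else:
        data = raw
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(["config must be a mapping"])
    errors: list[str] = []
    _check_keys(data, _TOP_KEYS, "", errors)

    kwargs: dict[str, Any] = {}
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "output_dir" in data:
        kwargs["output_dir"] = str(data["output_dir"])
    if "drop_minority_class" in data:
        kwargs["drop_minority_class"] = bool(data["drop_minority_class"])

    inp = data.get("input") or {}
    _check_keys(inp, _INPUT_KEYS, "input.", errors)
    if "path" in inp:
        kwargs["input_path"] = str(inp["path"])
    if "format" in inp:
        if inp["format"] not in ("delimited", "record_per_line"):
            errors.append("input.format: must be 'delimited' or 'record_per_line'")
        else:
            kwargs["input_format"] = inp["format"]
    if "text_field" in inp:
        kwargs["text_field"] = str(inp["text_field"])
    if "label_field" in inp:
        kwargs["label_field"] = str(inp["label_field"])

    synth_raw = data.get("synth")
    if synth_raw is not None:
        _check_keys(synth_raw, _SYNTH_KEYS, "synth.", errors)
        try:
            scale = float(synth_raw.get("scale", 1.0))
            fields = {k: v for k, v in synth_raw.items() if k not in ("scale", "class_counts")}
            if "class_names" in fields:
                fields["class_names"] = tuple(fields["class_names"])
            if "class_counts" in synth_raw:
                kwargs["synth"] = SynthSpec(
                    class_counts=tuple(synth_raw["class_counts"]), **fields
                )
            else:
                kwargs["synth"] = default_table1_spec(scale, **fields)
        except (ValueError, TypeError) as exc:
            errors.append(f"synth: {exc}")
    if kwargs.get("synth") is not None and kwargs.get("input_path"):
        errors.append("input.path and synth are mutually exclusive")
    if kwargs.get("synth") is None and not kwargs.get("input_path"):
        errors.append("either input.path or synth must be given")

    clean_raw = data.get("clean") or {}
    _check_keys(clean_raw, _CLEAN_KEYS, "clean.", errors)
    try:
        clean_fields = {k: v for k, v in clean_raw.items() if k != "stopword_file"}
        if "stopword_file" in clean_raw and clean_raw["stopword_file"]:
            words = Path(clean_raw["stopword_file"]).read_text("utf-8").split()
            clean_fields["stopword_list"] = frozenset(words)
        kwargs["clean"] = CleanConfig(**clean_fields)
    except (ValueError, TypeError, OSError) as exc:
        errors.append(f"clean: {exc}")

    vec = data.get("vectorize") or {}
    _check_keys(vec, _VEC_KEYS, "vectorize.", errors)
    if "ngram_orders" in vec:
        orders = tuple(int(n) for n in vec["ngram_orders"])
        if not orders or any(n not in (1, 2, 3) for n in orders):
            errors.append("vectorize.ngram_orders: must be a non-empty subset of {1,2,3}")
        else:
            kwargs["ngram_orders"] = orders
    if "weighting" in vec:
        if vec["weighting"] not in ("counts", "tfidf"):
            errors.append("vectorize.weighting: must be 'counts' or 'tfidf'")
        else:
            kwargs["weighting"] = vec["weighting"]

    split = data.get("split") or {}
    _check_keys(split, _SPLIT_KEYS, "split.", errors)
    if "test_fraction" in split:
        tf = float(split["test_fraction"])
        if not (0.0 < tf < 1.0):
            errors.append("split.test_fraction: must be in (0, 1)")
        else:
            kwargs["test_fraction"] = tf

    if "resample" in data:
        if data["resample"] not in ("oversample", "undersample", "none"):
            errors.append("resample: must be 'oversample', 'undersample', or 'none'")
        else:
            kwargs["resample_mode"] = data["resample"]

    fs = data.get("feature_selection") or {}
    _check_keys(fs, _FS_KEYS, "feature_selection.", errors)
    method = fs.get("method", "iwd")
    if method not in ("iwd", "none"):
        errors.append("feature_selection.method: must be 'iwd' or 'none'")
    else:
        kwargs["feature_selection"] = method
    try:
        kwargs["iwd"] = IWDParams(**{k: v for k, v in fs.items() if k != "method"})
    except (ValueError, TypeError) as exc:
        errors.append(f"feature_selection: {exc}")

    bp = data.get("bpnn") or {}
    _check_keys(bp, _BPNN_KEYS, "bpnn.", errors)
    try:
        bp_fields = dict(bp)
        if "hidden_sizes_grid" in bp_fields:
            bp_fields["hidden_sizes_grid"] = tuple(int(s) for s in bp_fields["hidden_sizes_grid"])
        kwargs["bpnn"] = BPNNConfig(**bp_fields)
    except (ValueError, TypeError) as exc:
        errors.append(f"bpnn: {exc}")

    if errors:
        raise ConfigError(errors)
    return PipelineConfig(**kwargs)


def _write_subset(path: Path, subset: FeatureSubset | None, names: tuple[str, ...]) -> None:
    with path.open("w", encoding="utf-8") as fh:
        if subset is None:
            fh.write("# feature selection disabled: all features used\n")
            fh.write("all\n")
            return
        fh.write(f"# selected features: {len(subset)}\n")
        fh.write(f"# fitness: {subset.fitness!r}\n")
        for idx in subset.indices:
            fh.write(f"{idx}\t{names[idx]}\n")


def _stage(name: str):
    """Decorator-free stage guard: wraps exceptions with the stage name."""

    class _Ctx:
        def __init__(self, stage_name: str):
            self.name = stage_name
            self.t0 = 0.0

        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", self.name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                if isinstance(exc, PipelineError):
                    return False
                raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", self.name, time.perf_counter() - self.t0)
            return False

    return _Ctx(name)


def run_pipeline(config: PipelineConfig, corpus: Corpus | None = None) -> EvalReport:
    """Execute every stage in order and persist all artifacts.

    A prebuilt ``corpus`` overrides the configured input source (useful when
    the corpus was generated separately with an explicit seed).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    with _stage("load"):
        if corpus is None:
            if config.synth is not None:
                log.info("generating synthetic corpus: %s", config.synth)
                corpus = synth_mod.generate(config.synth)
            else:
                assert config.input_path is not None
                corpus = read_corpus(
                    config.input_path,
                    config.input_format,
                    config.text_field,
                    config.label_field,
                )
        write_corpus(corpus, outdir / "corpus.csv", "delimited")

    if config.drop_minority_class:
        with _stage("drop_minority"):
            from .corpus import class_distribution

            dist = class_distribution(corpus)
            smallest = min(sorted(dist), key=lambda k: dist[k])
            log.info("dropping minority class %r (%d docs)", smallest, dist[smallest])
            corpus = Corpus([d for d in corpus if d.label != smallest])

    with _stage("clean"):
        cleaned = clean_corpus(corpus, config.clean)
        with (outdir / "cleaned.jsonl").open("w", encoding="utf-8") as fh:
            for doc in cleaned:
                fh.write(json.dumps({"tokens": list(doc.tokens), "label": doc.label}))
                fh.write("\n")

    with _stage("vectorize"):
        vocab = build_vocabulary(cleaned, config.ngram_orders)
        matrix = vectorize_counts(cleaned, vocab)
        if config.weighting == "tfidf":
            matrix = tfidf_weight(matrix)
        (outdir / "vocabulary.txt").write_text("\n".join(vocab.terms) + "\n", "utf-8")
        log.info("matrix: %d docs x %d features", matrix.n_docs, matrix.n_features)

    with _stage("split"):
        train_m, test_m = stratified_split(
            matrix, config.test_fraction, derive_seed(seed, "split")
        )

    # Feature selection sees the un-resampled training rows: oversampled
    # duplicates would straddle the wrapper's CV folds and let uninformative
    # features look predictive. Resampling happens afterwards, for the BPNN.
    subset: FeatureSubset | None = None
    if config.feature_selection == "iwd":
        with _stage("iwd_select"):
            params = replace(config.iwd, seed=derive_seed(seed, "iwd"))
            subset, trace, _ = run_iwd(train_m, params)
            with (outdir / "iwd_trace.csv").open("w", encoding="utf-8") as fh:
                fh.write("iteration,iteration_best_fitness,best_fitness\n")
                for row in trace:
                    fh.write(
                        f"{row['iteration']},{row['iteration_best_fitness']!r},"
                        f"{row['best_fitness']!r}\n"
                    )
            cols = list(subset.indices)
            train_sel = train_m.take_columns(cols)
            test_sel = test_m.take_columns(cols)
    else:
        train_sel, test_sel = train_m, test_m
    _write_subset(outdir / "selected_features.txt", subset, matrix.feature_names)

    if config.resample_mode != "none":
        with _stage("resample"):
            train_sel = resample(train_sel, config.resample_mode, derive_seed(seed, "resample"))
            log.info("training rows after %s: %d", config.resample_mode, train_sel.n_docs)

    with _stage("bpnn_train"):
        bp_config = replace(config.bpnn, seed=derive_seed(seed, "bpnn"))
        best_size, size_table = bpnn_mod.select_hidden_size(train_sel, bp_config)
        log.info("hidden-size validation RMSE: %s -> %d", size_table, best_size)
        model, history = bpnn_mod.train(train_sel, best_size, bp_config)
        with (outdir / "hidden_size_table.csv").open("w", encoding="utf-8") as fh:
            fh.write("n_hidden,validation_rmse\n")
            for size in sorted(size_table):
                fh.write(f"{size},{size_table[size]!r}\n")
        with (outdir / "rmse_history.csv").open("w", encoding="utf-8") as fh:
            fh.write("epoch,train_rmse,validation_rmse\n")
            for e, (tr, va) in enumerate(zip(history["train"], history["validation"])):
                fh.write(f"{e},{tr!r},{va!r}\n")
        save_model(model, outdir / "model.json")

    with _stage("evaluate"):
        y_pred = bpnn_mod.predict(model, test_sel)
        cm = confusion(test_sel.labels, y_pred, test_sel.class_names)
        report = metrics_from_confusion(cm)
        with (outdir / "confusion.csv").open("w", encoding="utf-8") as fh:
            fh.write("," + ",".join(cm.class_names) + "\n")
            for name, row in zip(cm.class_names, cm.counts):
                fh.write(name + "," + ",".join(str(v) for v in row) + "\n")
        (outdir / "report.json").write_text(report.as_json() + "\n", "utf-8")
        (outdir / "report.txt").write_text(report.as_text() + "\n", "utf-8")
    return report
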