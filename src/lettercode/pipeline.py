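"""End-to-end orchestration: synthesize -> preprocess -> letter code ->
string fits -> part-sum -> lexical models -> RSA.

A run is driven by a single :class:`RunConfig` (YAML-serialisable); every
stochastic stage has its own seed.  Each stage writes CSV/JSON artifacts
into ``<out_dir>/<stage>/`` and records a digest of its config section in
``manifest.json``; rerunning with an unchanged config skips stages whose
digests match (pass ``force=True`` to redo everything).  No stage mutates
its inputs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from lettercode import lexical, letters, partsum, preprocess, rsa, strings, synth
from lettercode._util import all_pairs

log = logging.getLogger("lettercode.pipeline")

STAGES = ["synth", "preprocess", "letters", "fit_strings", "partsum", "lexical", "rsa"]


@dataclass
class RunConfig:
    """Everything a full run needs.  Defaults give a small demo study."""

    out_dir: str = "runs/demo"
    alphabet: str = "ADHIMNRST"     # letters used to build strings
    n_neurons: int = 10
    # ground truth / synthesis
    seed_gt: int = 11
    seed_search: int = 21
    seed_lexicon: int = 31
    seed_lexical: int = 41
    seed_patterns: int = 51
    seed_embeddings: int = 61
    noise_sigma: float = 0.05       # lognormal sd of search-trial RT noise
    rt_scale: float = 1.0
    n_subjects_search: int = 6
    n_reps_search: int = 2
    n_bigram_letters: int = 7       # bigrams built from the first k alphabet letters
    n_words: int = 40               # per length
    word_lengths: tuple[int, ...] = (4, 5)
    zipf_exponent: float = 1.0
    edge_bias: float = 1.0          # ground-truth weights favour edge positions
    lexical_noise_sd: float = 0.03
    n_subjects_lexical: int = 8
    n_nonwords_per_category: int = 4
    # analysis knobs
    outlier_k: float = 3.0
    n_mds_dims: int = 10
    n_restarts: int = 5
    n_splits_reliability: int = 50
    n_boot_compare: int = 200
    n_boot_rsa: int = 500
    metric: str = "euclidean"
    # fMRI-like stage
    n_runs_patterns: int = 8
    n_voxels: int = 60
    pattern_noise_sd: float = 0.5
    emb_dims: int = 20
    emb_clusters: int = 4
    emb_noise_sd: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "word_lengths" in raw:
            raw["word_lengths"] = tuple(raw["word_lengths"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["word_lengths"] = list(d["word_lengths"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def digest(self) -> str:
        d = asdict(self)
        d["word_lengths"] = list(d["word_lengths"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]

    def validate(self) -> None:
        if self.n_bigram_letters > len(self.alphabet):
            raise ValueError("n_bigram_letters exceeds alphabet size")
        for s in (self.seed_gt, self.seed_search, self.seed_lexicon, self.seed_lexical,
                  self.seed_patterns, self.seed_embeddings):
            if not isinstance(s, int):
                raise ValueError("every stage seed must be an integer")


def _scheme_for(config: RunConfig) -> dict[str, dict[int, int]]:
    n = config.n_nonwords_per_category
    scheme: dict[str, dict[int, int]] = {}
    for cat in synth.STANDARD_NONWORD_SCHEME:
        per_len = {}
        for L in config.word_lengths:
            if cat.startswith("two_step") and L < 5:
                per_len[L] = 0
            else:
                per_len[L] = n
        scheme[cat] = per_len
    return scheme


class PipelineRun:
    """Executes stages, maintaining the run directory and manifest."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"stages": {}, "config_digest": None}

    # -- helpers -----------------------------------------------------------
    def _stage_dir(self, stage: str) -> Path:
        d = self.out / stage
        d.mkdir(exist_ok=True)
        return d

    def _done(self, stage: str) -> bool:
        rec = self.manifest["stages"].get(stage)
        return bool(rec) and rec["config_digest"] == self.config.digest()

    def _mark(self, stage: str, seconds: float) -> None:
        self.manifest["stages"][stage] = {
            "config_digest": self.config.digest(),
            "wall_time_s": round(seconds, 3),
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.manifest["config_digest"] = self.config.digest()
        import lettercode
        self.manifest["version"] = lettercode.__version__
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def run(self, stages: Sequence[str] | None = None, force: bool = False) -> Path:
        self.config.to_yaml(self.out / "config.yaml")
        for stage in stages or STAGES:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
            if not force and self._done(stage):
                log.info("stage %s up to date (digest match); skipping", stage)
                continue
            t0 = time.time()
            log.info("stage %s starting", stage)
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                raise RuntimeError(f"pipeline halted at stage {stage!r}: {exc}") from exc
            self._mark(stage, time.time() - t0)
            log.info("stage %s done in %.2fs", stage, time.time() - t0)
        return self.out

    # -- stages ------------------------------------------------------------
    def _ground_truth(self, length: int) -> synth.GroundTruth:
        cfg = self.config
        code = synth.make_letter_code(cfg.n_neurons, cfg.alphabet, cfg.seed_gt)
        w = synth.make_weights(cfg.n_neurons, length, cfg.seed_gt + length,
                               edge_bias=cfg.edge_bias)
        return synth.GroundTruth(letter_code=code, weights=w, rt_scale=cfg.rt_scale,
                                 noise_sigma=cfg.noise_sigma, seed=cfg.seed_gt)

    def stage_synth(self) -> None:
        cfg = self.config
        d = self._stage_dir("synth")
        # single-letter searches: strings of length 1 over the full alphabet
        gt1 = self._ground_truth(1)
        letter_pairs = all_pairs(list(cfg.alphabet))
        trials1 = synth.simulate_search_trials(gt1, letter_pairs, cfg.n_subjects_search,
                                               cfg.n_reps_search, cfg.seed_search)
        trials1.to_csv(d / "search_trials_letters.csv", index=False)
        # bigram searches over the first k letters
        gt2 = self._ground_truth(2)
        bigrams = ["".join(p) for p in
                   itertools.product(cfg.alphabet[: cfg.n_bigram_letters], repeat=2)]
        bigram_pairs = all_pairs(bigrams)
        trials2 = synth.simulate_search_trials(gt2, bigram_pairs, cfg.n_subjects_search,
                                               cfg.n_reps_search, cfg.seed_search + 1)
        trials2.to_csv(d / "search_trials_bigrams.csv", index=False)
        # lexicon, nonwords, lexical-decision trials
        lexica = [synth.make_lexicon(cfg.n_words, L, cfg.alphabet, cfg.zipf_exponent,
                                     cfg.seed_lexicon + L) for L in cfg.word_lengths]
        lexicon = synth.merge_lexica(lexica)
        pd.DataFrame({"word": lexicon.words, "frequency": lexicon.frequencies}
                     ).to_csv(d / "lexicon.csv", index=False)
        nonwords = synth.make_nonwords(lexicon, _scheme_for(cfg), cfg.seed_lexicon)
        nonwords.to_csv(d / "nonwords.csv", index=False)
        gts = {L: self._ground_truth(L) for L in cfg.word_lengths}
        gt_lex = gts[cfg.word_lengths[0]]
        weights_by_length = {L: gts[L].weights for L in cfg.word_lengths}
        trials_lex = synth.simulate_lexical_trials(
            gt_lex, lexicon, nonwords,
            synth.LexicalRTParams(noise_sd=cfg.lexical_noise_sd),
            cfg.n_subjects_lexical, cfg.seed_lexical,
            weights_by_length=weights_by_length)
        trials_lex.to_csv(d / "lexical_trials.csv", index=False)
        # voxel patterns for the words of the first length + embeddings
        words = sorted(lexicon.words_of_length(cfg.word_lengths[0]))
        rng = np.random.default_rng(cfg.seed_patterns)
        means = rng.standard_normal((len(words), cfg.n_voxels))
        patterns = synth.simulate_voxel_patterns(means, cfg.n_runs_patterns,
                                                 cfg.pattern_noise_sd, cfg.seed_patterns + 1,
                                                 condition_labels=words)
        np.save(d / "patterns.npy", patterns.data)   # runs x conditions x voxels
        (d / "pattern_conditions.json").write_text(json.dumps(words))
        emb = synth.make_embeddings(words, cfg.emb_dims, cfg.emb_clusters,
                                    cfg.seed_embeddings, cfg.emb_noise_sd)
        emb.to_csv(d / "embeddings.csv")
        # the generating ground truth, for reference
        gt1.letter_code.to_csv(d / "gt_letter_code.csv")
        for L, g in gts.items():
            g.weights.to_csv(d / f"gt_weights_len{L}.csv")

    def stage_preprocess(self) -> None:
        cfg = self.config
        d = self._stage_dir("preprocess")
        for name in ("letters", "bigrams"):
            trials = pd.read_csv(self.out / "synth" / f"search_trials_{name}.csv")
            filtered, report = preprocess.filter_outliers(trials, cfg.outlier_k)
            dis = preprocess.dissimilarity_from_trials(filtered)
            dis.to_csv(d / f"dissimilarity_{name}.csv", index=False)
            stats = preprocess.split_half_consistency(filtered, cfg.n_splits_reliability,
                                                      seed=cfg.seed_search)
            (d / f"reliability_{name}.json").write_text(json.dumps(
                {**report, "r_sh": stats.r_sh, "r_sh_sd": stats.r_sh_sd,
                 "r_data": stats.r_data, "r_odd_even": stats.r_odd_even}, indent=2))

    def stage_letters(self) -> None:
        cfg = self.config
        d = self._stage_dir("letters")
        dis = pd.read_csv(self.out / "preprocess" / "dissimilarity_letters.csv")
        n_letters = len(set(dis["item_a"]) | set(dis["item_b"]))
        n_dims = min(cfg.n_mds_dims, n_letters - 1)
        code = letters.embed_mds(dis, n_dims=n_dims)
        code.to_csv(d / "letter_code.csv")
        curve = letters.variance_explained_curve(dis, max_dims=n_letters - 1)
        curve.to_csv(d / "variance_explained.csv", index=False)
        (d / "mds_diagnostics.json").write_text(json.dumps(
            {**code.diagnostics, "n_dims": n_dims,
             "eigenvalues": code.eigenvalues.tolist()}, indent=2))

    def stage_fit_strings(self) -> None:
        cfg = self.config
        d = self._stage_dir("fit_strings")
        code = letters.LetterCode.from_csv(self.out / "letters" / "letter_code.csv")
        obs = pd.read_csv(self.out / "preprocess" / "dissimilarity_bigrams.csv")
        fit = strings.fit_weights(code, obs, metric=cfg.metric,
                                  n_restarts=cfg.n_restarts, seed=cfg.seed_gt)
        fit.params.to_csv(d / "weights_bigrams.csv")
        mi, mi_mean = strings.modulation_index(fit.params)
        (d / "fit_report.json").write_text(json.dumps(
            {"r": fit.r, "loss": fit.loss, "modulation_index_mean": mi_mean,
             "modulation_index": mi.tolist(), **fit.params.fit_meta}, indent=2))

    def stage_partsum(self) -> None:
        d = self._stage_dir("partsum")
        letter_d = pd.read_csv(self.out / "preprocess" / "dissimilarity_letters.csv")
        obs = pd.read_csv(self.out / "preprocess" / "dissimilarity_bigrams.csv")
        pairs = list(zip(obs["item_a"], obs["item_b"]))
        X, _ = partsum.build_design(letter_d, pairs)
        full = partsum.fit_part_sum(X, obs["d"].to_numpy())
        reduced = partsum.reduce_model(full.model, X, obs["d"].to_numpy())
        full.model.to_csv(d / "coefficients_full.csv")
        reduced.model.to_csv(d / "coefficients_reduced.csv")
        (d / "fit_report.json").write_text(json.dumps(
            {"r_full": full.r, "r_reduced": reduced.r,
             "rss_full": full.rss, "rss_reduced": reduced.rss,
             "n_params_full": full.model.n_free_params,
             "n_params_reduced": reduced.model.n_free_params}, indent=2))

    def stage_lexical(self) -> None:
        cfg = self.config
        d = self._stage_dir("lexical")
        trials = pd.read_csv(self.out / "synth" / "lexical_trials.csv")
        trials, removed = lexical.exclude_low_accuracy(trials)
        lex = pd.read_csv(self.out / "synth" / "lexicon.csv")
        nonwords = pd.read_csv(self.out / "synth" / "nonwords.csv")
        norms = lexical.LexicalNorms.from_lexicon(lex["word"], lex["frequency"])
        code = letters.LetterCode.from_csv(self.out / "letters" / "letter_code.csv")
        # per-length summation weights re-fit to reciprocal nonword RTs is a
        # heavier analysis; the pipeline uses the bigram-fitted code weights
        # pattern: equal weights per length as the default report baseline
        mean_rt = trials[trials["correct"].astype(bool)].groupby("string")["rt_s"].mean()
        words = [w for w in lex["word"] if w in mean_rt.index]
        feats = lexical.lexical_features(list(mean_rt.index), norms)
        # letter-model and OLD distances for nonwords
        weights_by_length = {
            L: strings.SpatialWeights(np.ones((code.n_dims, L)))
            for L in sorted({len(s) for s in mean_rt.index})}
        nw_list = [n for n in nonwords["nonword"] if n in mean_rt.index]
        dists, olds = {}, {}
        lexicon_words = list(lex["word"])
        for nw in nw_list:
            try:
                dists[nw], _ = lexical.nonword_distance(nw, lexicon_words, code,
                                                        weights_by_length)
            except ValueError:
                dists[nw] = np.nan
            olds[nw] = min(lexical.old_distance(nw, w) for w in lexicon_words)
        feats.loc[nw_list, "model_distance"] = pd.Series(dists)
        feats.loc[nw_list, "old_distance"] = pd.Series(olds)
        feats.to_csv(d / "features.csv")
        # word model comparison
        # drop predictors with no variance over the words of this study
        # (e.g. a sparse lexicon where no word has any orthographic neighbour)
        wf = feats.loc[words]
        usable = [p for p in lexical.WORD_PREDICTORS
                  if wf[p].notna().all() and wf[p].nunique() > 1]
        word_specs = [lexical.RTModelSpec(("log_word_freq",), "rt", "word_freq"),
                      lexical.RTModelSpec(tuple(usable), "rt", "combined")]
        word_trials = trials[trials["is_word"].astype(bool)]
        summary_w, p_w = lexical.crossval_compare(word_specs, word_trials, feats,
                                                  n_boot=cfg.n_boot_compare,
                                                  seed=cfg.seed_lexical)
        # nonword model comparison: letter model vs OLD
        nw_specs = [lexical.RTModelSpec(("model_distance",), "reciprocal_rt", "letter_model"),
                    lexical.RTModelSpec(("old_distance",), "reciprocal_rt", "old")]
        nw_trials = trials[~trials["is_word"].astype(bool)]
        nw_trials = nw_trials[nw_trials["string"].isin(
            feats.index[feats["model_distance"].notna()])]
        summary_n, p_n = lexical.crossval_compare(nw_specs, nw_trials, feats,
                                                  n_boot=cfg.n_boot_compare,
                                                  seed=cfg.seed_lexical + 1)
        tsum, tp = lexical.transposition_substitution_summary(trials, nonwords)
        tsum.to_csv(d / "transposition_substitution.csv")
        report = {
            "removed_low_accuracy": removed,
            "word_models": summary_w.reset_index().to_dict("records"),
            "word_exceedance_p": p_w.to_dict(),
            "nonword_models": summary_n.reset_index().to_dict("records"),
            "nonword_exceedance_p": p_n.to_dict(),
        }
        (d / "model_comparison.json").write_text(json.dumps(report, indent=2))

    def stage_rsa(self) -> None:
        cfg = self.config
        d = self._stage_dir("rsa")
        data = np.load(self.out / "synth" / "patterns.npy")
        conds = json.loads((self.out / "synth" / "pattern_conditions.json").read_text())
        patterns = rsa.PatternArray(data=data, condition_labels=conds,
                                    run_labels=[f"run_{i}" for i in range(data.shape[0])])
        neural = rsa.crossnobis(patterns)
        neural.to_csv(d / "crossnobis.csv", index=False)
        emb = pd.read_csv(self.out / "synth" / "embeddings.csv", index_col=0)
        semantic = rsa.semantic_dissimilarity_table(emb, conds)
        semantic.to_csv(d / "semantic.csv", index=False)
        # perceptual model: letter-model distances between the same words
        code = letters.LetterCode.from_csv(self.out / "letters" / "letter_code.csv")
        L = len(conds[0])
        w = strings.SpatialWeights(np.ones((code.n_dims, L)))
        pairs = all_pairs(conds)
        perc_d = [strings.model_dissimilarity(code, w, a, b) for a, b in pairs]
        from lettercode._util import dissim_table
        perceptual = dissim_table(pairs, np.array(perc_d))
        perceptual.to_csv(d / "perceptual.csv", index=False)
        r_p, sd_p, p_p = rsa.rsa_correlation(neural, perceptual, cfg.n_boot_rsa, cfg.seed_patterns)
        r_s, sd_s, p_s = rsa.rsa_correlation(neural, semantic, cfg.n_boot_rsa, cfg.seed_patterns)
        from lettercode._util import align_pair_tables
        xn, xp, xs = align_pair_tables(neural, perceptual, semantic)
        partial_np = rsa.partial_correlation(xn, xp, xs)
        partial_ns = rsa.partial_correlation(xn, xs, xp)
        (d / "rsa_report.json").write_text(json.dumps({
            "r_neural_perceptual": r_p, "sd_neural_perceptual": sd_p, "p_neural_perceptual": p_p,
            "r_neural_semantic": r_s, "sd_neural_semantic": sd_s, "p_neural_semantic": p_s,
            "partial_r_perceptual_given_semantic": partial_np,
            "partial_r_semantic_given_perceptual": partial_ns,
            "n_pairs": len(xn)}, indent=2))


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None,
                 force: bool = False) -> Path:
    """Run (part of) the pipeline; returns the run directory."""
    return PipelineRun(config).run(stages=stages, force=force)


# ---------------------------------------------------------------------------
# table validation


def validate_tables(paths: Sequence[str | Path]) -> list[dict]:
    """Schema and invariant checks for pipeline CSVs.

    Returns a list of violation records ({path, row, message}); empty for
    well-formed outputs.
    """
    violations: list[dict] = []

    def flag(path, row, message):
        violations.append({"path": str(path), "row": row, "message": message})

    for path in paths:
        path = Path(path)
        if not path.exists():
            flag(path, None, "file does not exist")
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            flag(path, None, f"unreadable CSV: {exc}")
            continue
        cols = set(df.columns)
        if "rt_s" in cols:
            bad = df.index[~(df["rt_s"] > 0)].tolist()
            for i in bad:
                flag(path, int(i), f"nonpositive rt_s: {df.loc[i, 'rt_s']}")
        if {"item_a", "item_b"}.issubset(cols):
            same = df.index[df["item_a"] == df["item_b"]].tolist()
            for i in same:
                flag(path, int(i), "item_a == item_b")
            if "d" in cols:
                dup = df.duplicated(subset=["item_a", "item_b"], keep=False)
                for i in df.index[dup].tolist():
                    flag(path, int(i), "duplicate pair row")
                for i in df.index[~(df["d"] > 0)].tolist():
                    if "crossnobis" not in path.name:   # crossnobis may be negative
                        flag(path, int(i), f"nonpositive dissimilarity: {df.loc[i, 'd']}")
        if "correct" in cols:
            for i in df.index[~df["correct"].isin([0, 1])].tolist():
                flag(path, int(i), "correct not in {0, 1}")
    return violations
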