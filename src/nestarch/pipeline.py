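"""End-to-end orchestration of the nest-architecture analysis.

Stages, in order: trait validation and recoding -> Gower/PCoA morphospace
-> climate PCA and predictor preparation (with VIF screening) ->
multivariate phylogenetic regression with RRPP -> regression scores and
trait-state association classes -> multivariate phylogenetic signal ->
univariate phylogenetic logistic suite. The CLI and the acceptance script
are thin wrappers around :func:`analyze`.

One root seed drives all stochastic stages through derived per-stage
streams, so results are reproducible and independent of stage order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import effects, morphospace, mvpgls, plogit, signal, traits
from .errors import AlignmentError, NestarchError
from .phylo import Phylogeny, PhyloCovariance, prune_and_align, read_newick_file, vcv

log = logging.getLogger("nestarch")

PREDICTOR_ORDER = (
    "climate_pc1",
    "climate_pc2",
    "predator_diversity",
    "island_endemic",
    "ndvi",
    "geo_mean_mass",
)


@dataclass
class AnalysisResult:
    """Everything the pipeline computes, ready for serialization."""

    recoded: list[traits.RecodedRecord]
    thresholds: traits.HeightThresholds
    rejects: pd.DataFrame
    space: morphospace.Morphospace
    variance: pd.DataFrame
    climate: effects.ClimatePcs
    predictors: pd.DataFrame
    vif: pd.Series
    fit: mvpgls.MvPglsFit
    scores: pd.DataFrame
    associations: pd.DataFrame
    signal: signal.PhyloSignalResult
    suite: pd.DataFrame
    congruence: pd.DataFrame

    def write(self, outdir) -> dict[str, Path]:
        """Serialize all statistical outputs (no timestamps: byte-stable)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _csv(name, frame, **kw):
            paths[name] = out / f"{name}.csv"
            frame.to_csv(paths[name], **kw)

        _csv("recoded_traits", traits.recoded_to_frame(self.recoded), index=False)
        _csv("rejects", self.rejects, index=False)
        _csv("variance_table", self.variance, index=False)
        _csv("morphospace", self.space.to_frame(), index_label="species_id")
        _csv("predictors", self.predictors, index_label="species_id")
        _csv("vif", self.vif.to_frame(), index_label="predictor")
        _csv("mvpgls_anova", self.fit.anova, index_label="term")
        _csv("mvpgls_coefficients", self.fit.coefficients, index_label="term")
        _csv("regression_scores", self.scores, index_label="species_id")
        _csv("associations", self.associations, index=False)
        _csv("univariate_suite", self.suite, index_label="trait_state")
        _csv("congruence", self.congruence, index=False)
        paths["signal"] = out / "phylo_signal.json"
        paths["signal"].write_text(self.signal.to_json() + "\n")
        import json

        paths["mvpgls"] = out / "mvpgls_fit.json"
        paths["mvpgls"].write_text(json.dumps(self.fit.to_json_dict(), indent=2) + "\n")
        return paths


def build_predictor_table(
    recoded: list[traits.RecodedRecord],
    raw_records: list[traits.NestRecord],
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, effects.ClimatePcs]:
    """Assemble the six-predictor table (unscaled) from its sources.

    Climate PCs come from a PCA of the five climate columns; island flag
    and geometric-mean body mass come from the trait records; NDVI and
    predator diversity pass through from the covariate table.
    """
    ids = [r.species_id for r in recoded]
    missing = [s for s in ids if s not in covariates.index]
    if missing:
        raise AlignmentError(f"species absent from covariate table: {missing[:10]}")
    cov = covariates.loc[ids]
    climate = effects.climate_pca(cov)
    island = {r.species_id: float(r.island_endemic) for r in raw_records}
    raw = pd.DataFrame(
        {
            "climate_pc1": climate.scores["pc1"],
            "climate_pc2": climate.scores["pc2"],
            "predator_diversity": cov["predator_diversity"],
            "island_endemic": [island[s] for s in ids],
            "ndvi": cov["ndvi"],
            "geo_mean_mass": [r.geo_mean_mass_g for r in recoded],
        },
        index=pd.Index(ids, name="species_id"),
    )
    return raw[list(PREDICTOR_ORDER)], climate


def analyze(
    records: list[traits.NestRecord],
    covariates: pd.DataFrame,
    tree: Phylogeny,
    seed: int,
    n_perm: int = 999,
    kmult_n_perm: int = 1000,
    rejects: pd.DataFrame | None = None,
    mass_outlier_exclude: tuple[str, ...] = (),
) -> AnalysisResult:
    """Run the full analysis on validated in-memory inputs."""
    rng = np.random.default_rng(seed)
    seed_fit = int(rng.integers(2**31 - 1))
    seed_signal = int(rng.integers(2**31 - 1))

    log.info("recoding %d nest records", len(records))
    recoded, thresholds = traits.recode_table(records)
    ids = [r.species_id for r in recoded]

    log.info("building morphospace (Gower + PCoA)")
    D = morphospace.gower(recoded)
    space = morphospace.pcoa(D)
    variance = morphospace.variance_table(space)
    log.info("retained %d morphospace axes", space.n_axes)

    log.info("preparing predictors (climate PCA, scaling)")
    raw_predictors, climate = build_predictor_table(recoded, records, covariates)
    predictors = mvpgls.prepare_predictors(raw_predictors)
    vif_table = mvpgls.vif(predictors)
    log.debug("VIF: %s", vif_table.to_dict())

    log.info("aligning tree with %d species", len(ids))
    pruned, _ = prune_and_align(tree, ids)
    C = vcv(pruned, order=ids)

    log.info("fitting multivariate PGLS (%d permutations)", n_perm)
    Y = space.to_frame()
    fit = mvpgls.fit(Y, predictors, C, n_perm=n_perm, seed=seed_fit)

    log.info("computing regression scores and associations")
    indicators = plogit.binarize_traits(recoded)
    score_frame = pd.DataFrame(
        {
            pred: effects.regression_scores(Y, fit, pred).scores
            for pred in fit.terms
        }
    )
    associations = effects.association_table(Y, fit, indicators)

    log.info("estimating multivariate phylogenetic signal")
    sig = signal.kmult(Y, C, n_perm=kmult_n_perm, seed=seed_signal)

    log.info("running univariate phylogenetic logistic suite")
    suite = plogit.run_univariate_suite(
        recoded, predictors, C, exclude=mass_outlier_exclude
    )
    congruence = plogit.congruence_report(suite, associations)

    return AnalysisResult(
        recoded=recoded,
        thresholds=thresholds,
        rejects=rejects if rejects is not None else pd.DataFrame(),
        space=space,
        variance=variance,
        climate=climate,
        predictors=predictors,
        vif=vif_table,
        fit=fit,
        scores=score_frame,
        associations=associations,
        signal=sig,
        suite=suite,
        congruence=congruence,
    )


def analyze_files(
    traits_csv,
    covariates_csv,
    tree_nwk,
    seed: int,
    n_perm: int = 999,
    kmult_n_perm: int = 1000,
) -> AnalysisResult:
    """File-based front end: read, validate, then run :func:`analyze`."""
    records, rejects = traits.read_nest_table(traits_csv)
    if not records:
        raise NestarchError("no valid nest records after validation")
    covariates = pd.read_csv(covariates_csv, index_col="species_id")
    tree = read_newick_file(tree_nwk)
    return analyze(
        records, covariates, tree, seed=seed, n_perm=n_perm,
        kmult_n_perm=kmult_n_perm, rejects=rejects,
    )
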