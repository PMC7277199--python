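"""End-to-end orchestration over the 14 (factor, PANSI) score pairs.

A full run scores the cohort, validates the BQREB and BSSA-10 item blocks,
writes a scale-level correlation matrix, and then, for every configured
(factor subscale, PANSI subscale) pair: fits the joint KDE, runs a seeded
Metropolis-Hastings chain started at a random individual's scores, discards
the burn-in, and bins the retained samples into joint and conditional
probability tables on the published grids.

Per-pair chains draw their seeds from independent streams derived from the
master seed and the pair index, so restricting the run to a subset of pairs
does not perturb the remaining pairs' results. A ``manifest.json`` records
the full configuration, package version, per-pair seeds and acceptance
rates; :func:`run_from_manifest` regenerates every output bitwise from the
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .instruments import (
    FACTOR_SUBSCALES,
    PANSI_SUBSCALES,
    ResponseMatrix,
    ScoreTable,
    builtin_specs,
    score_all,
    validate_responses,
)
from .kde import KdeModel, density, fit_kde
from .mcmc import (
    Chain,
    ChainConfig,
    acceptance_rate,
    discard_burnin,
    run_chain,
    suggested_proposal_scale,
)
from .prob_tables import (
    ProbabilityTable,
    bin_samples,
    builtin_grid,
    conditional_probabilities,
    joint_probabilities,
)
from .psychometrics import correlation_matrix, factor_report
from .synthetic import CohortSpec, generate_cohort

__all__ = ["RunConfig", "PairResult", "RunResult", "DEFAULT_PAIRS", "run_full", "run_from_manifest"]

logger = logging.getLogger(__name__)

#: the 14 score pairs analysed by default: each factor subscale against
#: both PANSI subscales
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (f, p) for f in FACTOR_SUBSCALES for p in PANSI_SUBSCALES
)


@dataclass
class RunConfig:
    """Configuration for a full run.

    Either ``input_csv`` (item-level responses) or ``cohort`` (a synthetic
    :class:`~pansimc.synthetic.CohortSpec`) supplies the data; ``seed`` is
    the master seed from which all per-pair chain seeds derive.
    """

    input_csv: str | None = None
    cohort: CohortSpec | None = None
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    iterations: int = 20_000
    burnin: int | None = None
    #: a float, or "auto" for the per-pair optimal-scaling rule
    proposal_scale: float | str = 1.0
    seed: int = 0
    output_dir: str = "pansimc_run"

    def __post_init__(self) -> None:
        self.pairs = tuple((str(f), str(p)) for f, p in self.pairs)
        for f, p in self.pairs:
            if f not in FACTOR_SUBSCALES or p not in PANSI_SUBSCALES:
                raise ValueError(
                    f"pair ({f}, {p}) must combine a factor subscale with a "
                    "PANSI subscale"
                )
        if self.input_csv is None and self.cohort is None:
            self.cohort = CohortSpec(seed=self.seed)

    def pair_seed(self, index: int) -> int:
        """Independent per-pair chain seed derived from the master seed."""
        return int(np.random.SeedSequence([self.seed, index]).generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        return {
            "input_csv": self.input_csv,
            "cohort": self.cohort.to_dict() if self.cohort else None,
            "pairs": [list(p) for p in self.pairs],
            "iterations": self.iterations,
            "burnin": self.burnin,
            "proposal_scale": self.proposal_scale,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict, output_dir: str | None = None) -> "RunConfig":
        cohort = None
        if d.get("cohort"):
            c = d["cohort"]
            import pandas as pd

            corr = pd.DataFrame(
                np.asarray(c["latent_corr"]["values"]),
                index=c["latent_corr"]["labels"],
                columns=c["latent_corr"]["labels"],
            )
            cohort = CohortSpec(
                n_respondents=c["n_respondents"],
                latent_corr=corr,
                loading=c["loading"],
                ceiling_skew=c["ceiling_skew"],
                seed=c["seed"],
            )
        return cls(
            input_csv=d.get("input_csv"),
            cohort=cohort,
            pairs=tuple(tuple(p) for p in d.get("pairs", DEFAULT_PAIRS)),
            iterations=d.get("iterations", 20_000),
            burnin=d.get("burnin"),
            proposal_scale=d.get("proposal_scale", 1.0),
            seed=d.get("seed", 0),
            output_dir=output_dir or d.get("output_dir", "pansimc_run"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path, output_dir: str | None = None) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), output_dir=output_dir)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PairResult:
    factor: str
    pansi: str
    kde: KdeModel
    chain: Chain
    joint: ProbabilityTable
    conditional: ProbabilityTable
    seed: int
    proposal_scale: float = 1.0


@dataclass
class RunResult:
    config: RunConfig
    scores: ScoreTable
    pair_results: dict[tuple[str, str], PairResult]
    manifest: dict
    failures: dict[tuple[str, str], str] = field(default_factory=dict)


def _load_responses(config: RunConfig) -> ResponseMatrix:
    if config.input_csv is not None:
        return ResponseMatrix.from_csv(config.input_csv)
    return generate_cohort(config.cohort)


def run_full(config: RunConfig) -> RunResult:
    """Execute every stage and write all artifacts under ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = builtin_specs()

    responses = _load_responses(config)
    responses.to_csv(out / "responses.csv")
    for spec in specs.values():
        rep = validate_responses(responses, spec)
        if rep.out_of_range:
            logger.warning("%s: %d out-of-range responses", spec.name, len(rep.out_of_range))

    scores = score_all(responses, specs)
    scores.to_csv(out / "scores.csv")

    corr = correlation_matrix(scores.scores)
    corr.to_dataframe().to_csv(out / "correlations.csv")

    psych = {}
    for inst_name in ("BQREB", "BSSA-10"):
        spec = specs[inst_name]
        df = responses.data[spec.columns]
        # item-level validation on the keyed (reverse-coded) responses
        keyed = df.copy()
        for sub, members in spec.subscales.items():
            for item_id, rev in members:
                if rev:
                    col = spec.column(item_id)
                    keyed[col] = spec.reverse(item_id, keyed[col])
        psych[inst_name] = factor_report(keyed).to_dict()
    with open(out / "psychometrics.json", "w") as fh:
        json.dump(psych, fh, indent=2)

    pair_results: dict[tuple[str, str], PairResult] = {}
    failures: dict[tuple[str, str], str] = {}
    pair_meta = []
    for idx, (fcol, pcol) in enumerate(config.pairs):
        seed = config.pair_seed(idx)
        try:
            pr = _run_pair(scores, fcol, pcol, config, seed, out)
        except Exception as exc:  # a failing pair must not sink the others
            logger.error("pair (%s, %s) failed: %s", fcol, pcol, exc)
            failures[(fcol, pcol)] = str(exc)
            continue
        pair_results[(fcol, pcol)] = pr
        pair_meta.append(
            {
                "factor": fcol,
                "pansi": pcol,
                "seed": seed,
                "n_scores": pr.kde.n,
                "bandwidths": list(pr.kde.bandwidths),
                "acceptance_rate": acceptance_rate(pr.chain),
                "burnin": pr.chain.burnin,
                "proposal_scale": pr.proposal_scale,
            }
        )

    manifest = {
        "package": "pansimc",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "pairs": pair_meta,
        "failures": {f"{k[0]}|{k[1]}": v for k, v in failures.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return RunResult(
        config=config,
        scores=scores,
        pair_results=pair_results,
        manifest=manifest,
        failures=failures,
    )


def _run_pair(
    scores: ScoreTable,
    fcol: str,
    pcol: str,
    config: RunConfig,
    seed: int,
    out: Path,
) -> PairResult:
    pts = scores.pair(fcol, pcol)
    model = fit_kde(pts)
    target = lambda x: density(model, x)  # noqa: E731
    if config.proposal_scale == "auto":
        scale = suggested_proposal_scale(pts)
    else:
        scale = float(config.proposal_scale)
    cc = ChainConfig(
        iterations=config.iterations,
        burnin=config.burnin,
        proposal_scale=scale,
        seed=seed,
        initial_state=None,  # random individual start
    )
    chain = run_chain(target, cc, scores=pts)
    retained = discard_burnin(chain)
    grid = builtin_grid(fcol, pcol)
    joint = joint_probabilities(bin_samples(retained, grid), grid)
    cond = conditional_probabilities(joint)

    stem = f"{fcol}__{pcol}"
    chain.to_csv(out / f"chain_{stem}.csv")
    joint.to_csv(out / f"joint_{stem}.csv", decimals=2)
    joint.to_csv(out / f"joint_{stem}_full.csv")
    cond.to_csv(out / f"conditional_{stem}.csv", decimals=2)
    cond.to_csv(out / f"conditional_{stem}_full.csv")
    return PairResult(
        factor=fcol, pansi=pcol, kde=model, chain=chain, joint=joint,
        conditional=cond, seed=seed, proposal_scale=scale,
    )


def run_from_manifest(manifest_path: str | Path, output_dir: str | Path) -> RunResult:
    """Regenerate a run, bitwise, from its manifest alone."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = RunConfig.from_dict(manifest["config"], output_dir=str(output_dir))
    return run_full(config)
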