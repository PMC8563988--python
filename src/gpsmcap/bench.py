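"""Synthetic target generators and the end-to-end capacity benchmark.

The benchmark mirrors the train -> generate -> evaluate workflow: a known
target distribution is materialized, disjoint training and target MSAs are
drawn from it on independent seeded streams, each requested model family is
fit to the training MSA, an evaluation MSA is generated from every fitted
model, and the full metric suite (covariance correlation, r20 / cc-r20,
Hamming + TVD, energy correlation, estimation bounds) is computed against
the target MSA.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .alphabet import reduced_alphabet
from .enumeration import SequenceDistribution
from .indep import IndepModel, fit_indep, indep_energy, sample_indep
from .metrics import (
    R20Result,
    cc_r20,
    covariance_correlation,
    energy_correlation,
    estimation_bound,
    hamming_report,
    r20,
)
from .msa import MSA
from .potts import (
    McmcSettings,
    PottsModel,
    enumerate_distribution,
    fit_potts,
    mcmc_sample,
    potts_energy,
)
from .stats import n_pairs
from .vae import VaeConfig, build_vae, sample_vae, train_vae, vae_logp

SCHEMA_VERSION = 1

# ---------------------------------------------------------------------------
# target generators


def random_potts(
    L: int,
    q: int,
    coupling_density: float = 0.3,
    coupling_scale: float = 0.6,
    field_scale: float = 0.3,
    seed: int = 0,
) -> PottsModel:
    """A random Potts target: Gaussian fields everywhere, Gaussian coupling
    blocks on a random subset of position pairs.

    ``coupling_density`` is the fraction of the L(L-1)/2 pairs that carry a
    coupling block; scales are the standard deviations of the entries.
    Deterministic under ``seed``.
    """
    if not 0.0 <= coupling_density <= 1.0:
        raise ValueError("coupling_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h = rng.normal(0.0, field_scale, size=(L, q))
    J = np.zeros((n_pairs(L), q, q))
    k = int(round(coupling_density * n_pairs(L)))
    coupled = rng.choice(n_pairs(L), size=k, replace=False)
    for p in coupled:
        J[p] = rng.normal(0.0, coupling_scale, size=(q, q))
    return PottsModel(h, J, reduced_alphabet(q))


def parity_target(n_bits: int, bias: float = 0.5) -> SequenceDistribution:
    """XOR target: i.i.d. bits at the first ``n_bits`` sites, last site equal
    to their parity.

    With the default ``bias = 0.5`` (uniform bits) every admissible word has
    probability ``2**-n_bits`` and all pairwise covariances vanish exactly,
    yet the (n_bits+1)-point structure is deterministic — the canonical
    pattern a pairwise model cannot represent.  A ``bias != 0.5`` makes the
    second letter appear with that probability at each bit, giving the word
    frequencies genuine variance, which correlation-based scores need.
    """
    if n_bits < 2:
        raise ValueError("n_bits must be >= 2")
    if not 0.0 < bias < 1.0:
        raise ValueError("bias must be in (0, 1)")
    L = n_bits + 1
    from .enumeration import all_sequences

    seqs = all_sequences(L, 2)
    parity = seqs[:, :n_bits].sum(axis=1) % 2
    admissible = seqs[:, n_bits] == parity
    ones = seqs[:, :n_bits].sum(axis=1)
    probs = np.where(admissible, bias**ones * (1 - bias) ** (n_bits - ones), 0.0)
    return SequenceDistribution(probs, L, 2, reduced_alphabet(2), seqs)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class BenchmarkConfig:
    """Everything a benchmark run needs; YAML-serializable flat mapping."""

    # target
    L: int = 20
    q: int = 6
    target: str = "potts"  # "potts" | "parity" | path to a saved Potts model
    coupling_density: float = 0.3
    coupling_scale: float = 0.6
    field_scale: float = 0.3
    parity_bits: int = 4
    # dataset sizes
    training_sizes: tuple[int, ...] = (1_000, 100_000)
    n_target: int = 100_000
    n_eval: int = 100_000
    n_test: int = 1_000
    hamming_size: int = 10_000
    # models and metric settings
    models: tuple[str, ...] = ("potts", "indep")
    word_lengths: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_sets: int = 200
    top_k: int = 20
    compute_cc: bool = False
    compute_bound: bool = True
    # potts fitting / sampling
    potts_max_iters: int = 200
    potts_step: float = 0.2
    potts_fit_chains: int = 3072
    potts_sweeps_per_iter: int = 4
    sample_chains: int = 2048
    sample_burn: int = 300
    sample_thin: int = 5
    # vae
    vae_hidden: tuple[int, ...] = (100, 100, 100)
    vae_latent: int = 7
    vae_epochs: int = 16
    vae_batch: int = 200
    vae_lr: float = 1e-3
    vae_logp_samples: int = 500
    # randomness
    master_seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "BenchmarkConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f_.name for f_ in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("training_sizes", "models", "word_lengths", "vae_hidden"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=True)


# deterministic per-stage seed derivation: the master seed is combined with a
# CRC of the stage name, so adding or removing one stage never perturbs the
# random stream of another.
def stage_seed(master_seed: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode())
    ss = np.random.SeedSequence([int(master_seed), tag])
    return int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)


# ---------------------------------------------------------------------------
# reports


@dataclass
class CapacityReport:
    """All metric outcomes for one (model, training size) combination."""

    model: str
    train_size: int
    covariance: dict
    r20: dict
    hamming: dict
    energy: dict
    cc_r20: dict | None = None
    bounds: dict | None = None
    metadata: dict = field(default_factory=dict)
    incomplete: bool = False

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "model": self.model,
            "train_size": self.train_size,
            "covariance": self.covariance,
            "r20": self.r20,
            "cc_r20": self.cc_r20,
            "hamming": self.hamming,
            "energy": self.energy,
            "bounds": self.bounds,
            "metadata": self.metadata,
            "incomplete": self.incomplete,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CapacityReport":
        return cls(
            model=d["model"],
            train_size=d["train_size"],
            covariance=d["covariance"],
            r20=d["r20"],
            hamming=d["hamming"],
            energy=d["energy"],
            cc_r20=d.get("cc_r20"),
            bounds=d.get("bounds"),
            metadata=d.get("metadata", {}),
            incomplete=d.get("incomplete", False),
        )


def write_report(
    report: CapacityReport | list[CapacityReport], path: str | Path
) -> None:
    """Serialize report(s) to deterministic JSON (sorted keys, no timestamps)."""
    if isinstance(report, CapacityReport):
        payload = {"schema_version": SCHEMA_VERSION, "reports": [report.to_dict()]}
    else:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "reports": [r.to_dict() for r in report],
        }
    with open(path, "w") as f:
        json.dump(payload, f, sort_keys=True, indent=1)
        f.write("\n")


def read_report(path: str | Path) -> list[CapacityReport]:
    with open(path) as f:
        payload = json.load(f)
    return [CapacityReport.from_dict(d) for d in payload["reports"]]


# ---------------------------------------------------------------------------
# benchmark driver


class _Target:
    """Uniform sampling/energy interface over the possible target kinds."""

    def __init__(self, config: BenchmarkConfig):
        self.config = config
        self.kind = config.target
        if self.kind == "parity":
            self.dist = parity_target(config.parity_bits)
            self.model = None
            self.L, self.q = self.dist.L, self.dist.q
            self.alphabet = self.dist.alphabet
        else:
            if self.kind == "potts":
                model = random_potts(
                    config.L,
                    config.q,
                    config.coupling_density,
                    config.coupling_scale,
                    config.field_scale,
                    seed=stage_seed(config.master_seed, "target_model"),
                )
            else:
                model = PottsModel.load(self.kind)
            self.model = model
            self.L, self.q = model.L, model.q
            self.alphabet = model.alphabet
            self.dist = (
                enumerate_distribution(model) if self.q**self.L <= 2_000_000 else None
            )

    def sample(self, n: int, seed: int) -> MSA:
        if self.dist is not None:
            return self.dist.sample(n, seed)
        cfg = self.config
        settings = McmcSettings(
            n_chains=cfg.sample_chains,
            burn_in_sweeps=cfg.sample_burn,
            thin_sweeps=cfg.sample_thin,
            seed=seed,
        )
        return mcmc_sample(self.model, n, settings)

    def energies(self, msa: MSA) -> np.ndarray:
        if self.model is not None:
            return potts_energy(self.model, msa)
        return self.dist.neg_log_prob(msa)


def _fit_and_sample(
    name: str, target: _Target, train: MSA, config: BenchmarkConfig, seed_eval: int
):
    """Fit one model family and generate its evaluation MSA."""
    cfg = config
    if name == "indep":
        model = fit_indep(train)
        eval_msa = sample_indep(model, cfg.n_eval, seed_eval)
        energy_fn = lambda msa: indep_energy(model, msa)
    elif name == "potts":
        settings = McmcSettings(
            n_chains=cfg.potts_fit_chains,
            burn_in_sweeps=100,
            thin_sweeps=1,
            seed=stage_seed(cfg.master_seed, f"fit_potts_{train.N}"),
        )
        model = fit_potts(
            train,
            settings=settings,
            max_iters=cfg.potts_max_iters,
            step=cfg.potts_step,
            sweeps_per_iter=cfg.potts_sweeps_per_iter,
        )
        if target.q**target.L <= 2_000_000:
            eval_msa = enumerate_distribution(model).sample(cfg.n_eval, seed_eval)
        else:
            eval_msa = mcmc_sample(
                model,
                cfg.n_eval,
                McmcSettings(
                    n_chains=cfg.sample_chains,
                    burn_in_sweeps=cfg.sample_burn,
                    thin_sweeps=cfg.sample_thin,
                    seed=seed_eval,
                ),
            )
        energy_fn = lambda msa: potts_energy(model, msa)
    elif name == "vae":
        vcfg = VaeConfig(
            L=target.L,
            q=target.q,
            hidden_sizes=cfg.vae_hidden,
            latent_dim=cfg.vae_latent,
            batch_size=cfg.vae_batch,
            epochs=cfg.vae_epochs,
            learning_rate=cfg.vae_lr,
            seed=stage_seed(cfg.master_seed, f"vae_{train.N}"),
        )
        model = train_vae(build_vae(vcfg, target.alphabet), train)
        eval_msa = sample_vae(model, cfg.n_eval, seed_eval)
        energy_fn = lambda msa: vae_logp(
            model,
            msa,
            n_importance=cfg.vae_logp_samples,
            seed=stage_seed(cfg.master_seed, f"vae_logp_{train.N}"),
        )
    else:
        raise ValueError(f"unknown model family {name!r}")
    return model, eval_msa, energy_fn


def run_benchmark(config: BenchmarkConfig, verbose: bool = False) -> list[CapacityReport]:
    """Execute the full workflow; one report per (model, training size)."""
    cfg = config
    target = _Target(cfg)
    log = print if verbose else (lambda *a, **k: None)

    log(f"target: {cfg.target} L={target.L} q={target.q}")
    target_msa = target.sample(cfg.n_target, stage_seed(cfg.master_seed, "target_msa"))
    test_msa = target.sample(cfg.n_test, stage_seed(cfg.master_seed, "test_msa"))
    target_energies = target.energies(test_msa)
    target_hamming = hamming_report(
        target.sample(cfg.hamming_size, stage_seed(cfg.master_seed, "hamming_target"))
    )

    bounds = None
    if cfg.compute_bound:
        b = estimation_bound(
            target.sample,
            cfg.n_target,
            cfg.n_eval,
            lambda a, e: r20(a, e, cfg.word_lengths, cfg.n_sets, cfg.top_k,
                             stage_seed(cfg.master_seed, "r20_sets")),
            seed_a=stage_seed(cfg.master_seed, "bound_a"),
            seed_b=stage_seed(cfg.master_seed, "bound_b"),
        )
        bounds = {"r20": b.to_dict()}
        log(f"estimation bound r20: {np.round(b.mean_scores, 4)}")

    reports = []
    for size in cfg.training_sizes:
        train = target.sample(size, stage_seed(cfg.master_seed, f"train_{size}"))
        for name in cfg.models:
            log(f"fitting {name} on {size} sequences ...")
            seed_eval = stage_seed(cfg.master_seed, f"eval_{name}_{size}")
            model, eval_msa, energy_fn = _fit_and_sample(
                name, target, train, cfg, seed_eval
            )
            cov = covariance_correlation(eval_msa, target_msa)
            scores = r20(
                target_msa,
                eval_msa,
                cfg.word_lengths,
                cfg.n_sets,
                cfg.top_k,
                stage_seed(cfg.master_seed, "r20_sets"),
            )
            cc = None
            if cfg.compute_cc:
                cc = cc_r20(
                    target_msa,
                    eval_msa,
                    [n for n in cfg.word_lengths if n <= 5],
                    cfg.n_sets,
                    cfg.top_k,
                    stage_seed(cfg.master_seed, "r20_sets"),
                ).to_dict()
            eval_hamming = hamming_report(
                eval_msa.take(np.arange(min(cfg.hamming_size, eval_msa.N)))
            )
            from .metrics import tvd as _tvd

            ham = {
                "target_hist": target_hamming["hist"],
                "eval_hist": eval_hamming["hist"],
                "tvd": _tvd(
                    np.array(target_hamming["hist"]), np.array(eval_hamming["hist"])
                ),
                "target_mode": target_hamming["mode"],
                "eval_mode": eval_hamming["mode"],
            }
            erho = energy_correlation(energy_fn(test_msa), target_energies)
            fit_info = {}
            if name == "potts" and getattr(model, "fit_report", None) is not None:
                fr = model.fit_report
                fit_info = {
                    "converged": bool(fr.converged),
                    "iterations": int(fr.iterations),
                    "final_discrepancy": float(fr.final_discrepancy),
                }
            reports.append(
                CapacityReport(
                    model=name,
                    train_size=size,
                    covariance={
                        "rho": cov.rho,
                        "slope": cov.slope,
                        "degenerate": cov.degenerate,
                    },
                    r20=scores.to_dict(),
                    cc_r20=cc,
                    hamming=ham,
                    energy={"rho": erho.rho, "degenerate": erho.degenerate},
                    bounds=bounds,
                    metadata={
                        "master_seed": cfg.master_seed,
                        "seeds": {
                            "eval": seed_eval,
                            "target_msa": stage_seed(cfg.master_seed, "target_msa"),
                            "train": stage_seed(cfg.master_seed, f"train_{size}"),
                            "test_msa": stage_seed(cfg.master_seed, "test_msa"),
                            "r20_sets": stage_seed(cfg.master_seed, "r20_sets"),
                        },
                        "sizes": {
                            "train": size,
                            "target": cfg.n_target,
                            "eval": cfg.n_eval,
                            "test": cfg.n_test,
                            "hamming": cfg.hamming_size,
                        },
                        "target": {"kind": cfg.target, "L": target.L, "q": target.q},
                        "fit": fit_info,
                    },
                )
            )
            log(
                f"  {name}@{size}: cov rho={cov.rho:.3f} "
                f"r20={np.round(scores.mean_scores, 3)} tvd={ham['tvd']:.4f} "
                f"E rho={erho.rho:.3f}"
            )
    return reports
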