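"""Per-codon Bayesian decision over amino-acid decoding models.

For each codon the evidence is the set of consensus-column emission
vectors aligned to it.  Twenty-one hypotheses compete: model ``M_a`` says
the codon is translated specifically as amino acid ``a``, so column ``i``
contributes likelihood ``pi_i(a)``; the non-specific model ``M_0`` says
the alignments reflect background usage, contributing
``sum_a f(a) * pi_i(a)`` for background composition ``f``.  Columns are
treated as independent, the prior over models is uniform by default, and
an amino acid is reported only when its posterior reaches the decision
threshold (default 0.9999); otherwise the codon stays uninferred ('?').
The non-specific model can never be "decided", and '*' is never emitted —
stop codons are expected to come out '?', and a sense codon that has
become a stop is undetectable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codes import AA_ALPHABET, CODONS, GeneticCode, compare_codes
from .errors import InvalidDistributionError
from .observe import CodonObservation, ObservationSet

N_MODELS = 21  # 20 amino-acid models followed by the non-specific model

DEFAULT_THRESHOLD = 0.9999


@dataclass
class InferenceConfig:
    """Decision parameters for codon inference.

    ``threshold`` is the posterior an amino-acid model must reach for a
    call; ``prior`` is over the 21 models (amino-acid order then the
    non-specific model); ``background`` is the amino-acid composition
    ``f`` used by the non-specific model, normally the profile-database
    mean background.
    """

    threshold: float = DEFAULT_THRESHOLD
    prior: np.ndarray | None = None
    background: np.ndarray | None = None
    emission_floor: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold <= 1.0:
            raise InvalidDistributionError(
                f"threshold {self.threshold} outside (0.5, 1]"
            )
        if self.prior is None:
            self.prior = np.full(N_MODELS, 1.0 / N_MODELS)
        else:
            self.prior = np.asarray(self.prior, dtype=float)
            if self.prior.shape != (N_MODELS,) or abs(self.prior.sum() - 1) > 1e-9:
                raise InvalidDistributionError("prior must be 21 probabilities summing to 1")
        if self.background is None:
            self.background = np.full(20, 0.05)
        else:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != (20,) or abs(self.background.sum() - 1) > 1e-9:
                raise InvalidDistributionError(
                    "background must be 20 probabilities summing to 1"
                )


@dataclass
class CodonPosterior:
    """Posterior over the 21 decoding models for one codon."""

    codon_idx: int
    n_observations: int
    log_likelihoods: np.ndarray = field(repr=False)
    posteriors: np.ndarray = field(repr=False)
    decision: str = "?"

    @property
    def codon(self) -> str:
        return CODONS[self.codon_idx]

    @property
    def top_model(self) -> str:
        """Label of the maximum-posterior model ('ns' = non-specific)."""
        k = int(np.argmax(self.posteriors))
        return AA_ALPHABET[k] if k < 20 else "ns"

    @property
    def top_posterior(self) -> float:
        return float(np.max(self.posteriors))


def codon_log_likelihoods(
    observations: list[CodonObservation], background: np.ndarray
) -> np.ndarray:
    """Natural-log likelihood of each of the 21 models given the evidence.

    Amino-acid model ``a``: sum of ``log pi_i(a)``; non-specific model:
    sum of ``log(f . pi_i)``.  An empty observation list is an empty
    product — all 21 log likelihoods are 0.
    """
    out = np.zeros(N_MODELS)
    if not observations:
        return out
    em = np.vstack([obs.emission for obs in observations])  # (n, 20)
    with np.errstate(divide="ignore"):
        out[:20] = np.log(em).sum(axis=0)
        out[20] = np.log(em @ background).sum()
    return out


def codon_posterior(
    log_likelihoods: np.ndarray,
    config: InferenceConfig,
    codon_idx: int = 0,
    n_observations: int = 0,
) -> CodonPosterior:
    """Posterior over models and the threshold decision for one codon.

    ``-inf`` log likelihoods (from exact-zero emissions) are handled;
    NaN is rejected.  The decision is the argmax amino acid iff its
    posterior reaches the threshold; if the non-specific model is the
    argmax, or nothing reaches the threshold, the codon stays '?'.
    """
    ll = np.asarray(log_likelihoods, dtype=float)
    if ll.shape != (N_MODELS,) or np.isnan(ll).any():
        raise InvalidDistributionError("need 21 non-NaN log likelihoods")
    with np.errstate(divide="ignore"):
        logpost = ll + np.log(config.prior)
    m = np.max(logpost)
    if not np.isfinite(m):
        raise InvalidDistributionError("all models have zero posterior mass")
    w = np.exp(logpost - m)
    posteriors = w / w.sum()
    best = int(np.argmax(posteriors))
    decision = "?"
    if best < 20 and posteriors[best] >= config.threshold:
        decision = AA_ALPHABET[best]
    return CodonPosterior(
        codon_idx=codon_idx,
        n_observations=n_observations,
        log_likelihoods=ll,
        posteriors=posteriors,
        decision=decision,
    )


def infer_code(
    obs_set: ObservationSet, config: InferenceConfig | None = None
) -> tuple[GeneticCode, list[CodonPosterior]]:
    """Infer the full 64-codon table from grouped observations.

    Codons with no observations (the expected case for stop codons)
    come out '?'; '*' is never produced.
    """
    if config is None:
        config = InferenceConfig()
    posteriors = []
    letters = []
    for idx in range(64):
        observations = obs_set.by_codon[idx]
        ll = codon_log_likelihoods(observations, config.background)
        cp = codon_posterior(ll, config, idx, len(observations))
        posteriors.append(cp)
        letters.append(cp.decision)
    return GeneticCode(name="inferred", table="".join(letters)), posteriors


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_code_string(code: GeneticCode, path: str | Path) -> None:
    Path(path).write_text(code.table + "\n")


def write_report(posteriors: list[CodonPosterior], path: str | Path) -> None:
    """Per-codon TSV: codon, n_observations, top model, posterior, decision."""
    with open(path, "w") as fh:
        fh.write("#codon\tn_observations\ttop_model\tposterior\tdecision\n")
        for cp in posteriors:
            fh.write(
                f"{cp.codon}\t{cp.n_observations}\t{cp.top_model}\t"
                f"{cp.top_posterior:.6f}\t{cp.decision}\n"
            )


def write_diff(
    inferred: GeneticCode, reference: GeneticCode, path: str | Path
) -> None:
    """Human-readable diff versus a reference table (1-based codon shown)."""
    diffs = compare_codes(inferred, reference)
    with open(path, "w") as fh:
        fh.write(f"# inferred vs {reference.name}: {len(diffs)} differences\n")
        fh.write("#codon\treference\tinferred\tcategory\n")
        for d in diffs:
            fh.write(f"{d.codon}\t{d.reference}\t{d.inferred}\t{d.category}\n")
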