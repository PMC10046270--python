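"""Refitting a fixed set of COSMIC SBS signatures to a mutation catalog.

The model is a mixture of multinomials: each of the N mutations in a
catalog is generated by signature k with probability pi_k and then falls in
channel c with probability s_kc.  With the signature matrix S fixed, the
exposures pi maximizing the log-likelihood

    l(pi) = sum_c n_c * log( sum_k pi_k * s_kc )

are found by expectation-maximization from a uniform start:

    E-step:  r_kc = pi_k s_kc / sum_j pi_j s_jc
    M-step:  pi_k <- sum_c n_c r_kc / N

The same responsibilities give a per-mutation posterior over signatures,
used to call individual mutations UV-related when the posterior mass on
the UV signatures (SBS7a/b/c/d, SBS38) reaches 0.5.

Exposure-level etiology bands summarize a fit qualitatively: UV signature
predominant vs minor, an APOBEC flag (SBS2+SBS13) and a three-level
homologous-recombination-deficiency band from the SBS3 exposure.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

from .catalog import MutationCatalog
from .formats_io import CHANNEL_INDEX, SignatureMatrix

__all__ = [
    "ExposureVector",
    "EtiologySummary",
    "UV_SIGNATURES",
    "APOBEC_SIGNATURES",
    "HRD_SIGNATURE",
    "MELANOMA_SIGNATURES",
    "em_fit",
    "attribute_mutation",
    "etiology_summary",
]

#: UV-associated single-base-substitution signatures.  The doublet signature
#: DBS1 is also UV-associated but lives outside the 96-channel SBS space and
#: is therefore not part of this SNV-only pipeline.
UV_SIGNATURES = frozenset({"SBS7a", "SBS7b", "SBS7c", "SBS7d", "SBS38"})
APOBEC_SIGNATURES = frozenset({"SBS2", "SBS13"})
HRD_SIGNATURE = "SBS3"

#: Candidate list of signatures frequently identified in melanoma, the
#: default starting set for refitting.
MELANOMA_SIGNATURES = (
    "SBS1", "SBS2", "SBS3", "SBS5", "SBS7a", "SBS7b", "SBS7c", "SBS7d",
    "SBS13", "SBS17a", "SBS17b", "SBS38", "SBS40",
)


@dataclass
class ExposureVector:
    """Mixture weights pi_k over a signature set, plus fit diagnostics."""

    signature_ids: tuple[str, ...]
    proportions: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    #: per-iteration log-likelihood of the (final) EM pass, for diagnostics
    ll_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (len(self.signature_ids),):
            raise ValueError("proportions length does not match signature_ids")
        if (self.proportions < 0).any():
            raise ValueError("negative exposure")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError(f"exposures sum to {self.proportions.sum()!r}, not 1")

    def __getitem__(self, signature_id: str) -> float:
        """Exposure of *signature_id*; absent signatures contribute 0."""
        try:
            return float(self.proportions[self.signature_ids.index(signature_id)])
        except ValueError:
            return 0.0

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(self.signature_ids, self.proportions)}


@dataclass(frozen=True)
class EtiologySummary:
    """Qualitative banding of a signature fit."""

    uv_share: float
    uv_band: str  # "predominant" | "minor"
    apobec_flag: bool
    hrd_band: str  # "none" | "minor" | "present"


def _log_likelihood(counts: np.ndarray, mix: np.ndarray) -> float:
    nz = counts > 0
    return float(np.dot(counts[nz], np.log(mix[nz])))


def _em_core(
    counts: np.ndarray, S: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, int, bool, list[float]]:
    k = S.shape[0]
    n = counts.sum()
    pi = np.full(k, 1.0 / k)
    mix = pi @ S
    ll = _log_likelihood(counts, mix)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step responsibilities folded into the M-step update:
        # pi_k <- (1/N) sum_c n_c * pi_k s_kc / mix_c
        with np.errstate(invalid="ignore", divide="ignore"):
            weights = np.where(counts > 0, counts / mix, 0.0)
        pi = pi * (S @ weights) / n
        pi = np.clip(pi, 0.0, None)
        pi /= pi.sum()
        mix = pi @ S
        new_ll = _log_likelihood(counts, mix)
        trace.append(new_ll)
        if new_ll - ll < tol:
            ll = max(new_ll, ll)
            converged = True
            break
        ll = new_ll
    return pi, ll, it, converged, trace


def em_fit(
    catalog: MutationCatalog,
    signatures: SignatureMatrix,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    prune_threshold: float = 0.01,
    prune: bool = True,
) -> ExposureVector:
    """Maximum-likelihood exposures of *signatures* for *catalog* via EM.

    Starts from uniform exposures (the likelihood is concave in the mixture
    distribution, so the fit is insensitive to the start) and stops when the
    log-likelihood improves by less than *tol* or after *max_iter*
    iterations.  With *prune*, signatures whose fitted exposure falls below
    *prune_threshold* are dropped and the fit repeated once on the reduced
    set; pruned signatures are reported at exposure 0.

    Raises ``ValueError`` on an empty catalog or when some observed channel
    is unreachable by every signature (the likelihood would be -inf).
    """
    counts = catalog.counts.astype(float)
    if counts.sum() < 1:
        raise ValueError("cannot fit an empty catalog")
    S = signatures.probs
    unreachable = (counts > 0) & (S.sum(axis=0) == 0)
    if unreachable.any():
        ch = signatures.channel_labels[int(np.argmax(unreachable))]
        raise ValueError(f"observed channel {ch} unreachable by all signatures")

    if signatures.k == 1:
        mix = S[0]
        ll = _log_likelihood(counts, mix)
        return ExposureVector(
            signature_ids=signatures.signature_ids,
            proportions=np.array([1.0]),
            log_likelihood=ll,
            n_iterations=1,
            converged=True,
            ll_trace=np.array([ll]),
        )

    pi, ll, it, converged, trace = _em_core(counts, S, tol, max_iter)

    if prune:
        keep = pi >= prune_threshold
        if keep.sum() == 0:  # pathological threshold; keep the best signature
            keep[np.argmax(pi)] = True
        if not keep.all():
            sub = S[keep]
            pi_sub, ll, it2, converged, trace = _em_core(counts, sub, tol, max_iter)
            it += it2
            pi = np.zeros_like(pi)
            pi[keep] = pi_sub

    return ExposureVector(
        signature_ids=signatures.signature_ids,
        proportions=pi / pi.sum(),
        log_likelihood=ll,
        n_iterations=it,
        converged=converged,
        ll_trace=np.asarray(trace),
    )


def attribute_mutation(
    channel: str,
    exposures: ExposureVector,
    signatures: SignatureMatrix,
) -> tuple[dict[str, float], float]:
    """Posterior signature responsibility for one mutation channel.

    Returns ``(posterior, uv_posterior)`` where
    ``posterior[k] = pi_k s_kc / sum_j pi_j s_jc`` and *uv_posterior* is the
    total posterior mass on the UV signatures.  A mutation is called
    UV-related when ``uv_posterior >= 0.5``.
    """
    if exposures.signature_ids != signatures.signature_ids:
        raise ValueError("exposures and signatures disagree on signature ids")
    c = CHANNEL_INDEX[channel]
    weights = exposures.proportions * signatures.probs[:, c]
    denom = weights.sum()
    if denom == 0:
        raise ValueError(f"channel {channel} has zero probability under the fit")
    post = weights / denom
    posterior = {s: float(p) for s, p in zip(signatures.signature_ids, post)}
    uv_posterior = float(sum(p for s, p in posterior.items() if s in UV_SIGNATURES))
    return posterior, uv_posterior


def is_uv_related(uv_posterior: float, cutoff: float = 0.5) -> bool:
    """UV call for one mutation; ties at the cutoff are called UV-related."""
    return uv_posterior >= cutoff


def etiology_summary(
    exposures: ExposureVector,
    *,
    uv_predominant_cutoff: float = 0.5,
    apobec_cutoff: float = 0.10,
    hrd_minor_cutoff: float = 0.05,
    hrd_present_cutoff: float = 0.20,
) -> EtiologySummary:
    """Band a signature fit into the qualitative etiology vocabulary.

    UV share is the summed exposure of SBS7a-d and SBS38 and is
    "predominant" at or above *uv_predominant_cutoff*, else "minor".  The
    APOBEC flag fires when SBS2+SBS13 reach *apobec_cutoff*.  The HRD band
    follows the SBS3 exposure: none below *hrd_minor_cutoff*, minor up to
    *hrd_present_cutoff*, present above it.  Signatures absent from the fit
    contribute zero.
    """
    uv_share = float(sum(exposures[s] for s in sorted(UV_SIGNATURES)))
    apobec = sum(exposures[s] for s in sorted(APOBEC_SIGNATURES))
    sbs3 = exposures[HRD_SIGNATURE]
    if sbs3 < hrd_minor_cutoff:
        hrd_band = "none"
    elif sbs3 <= hrd_present_cutoff:
        hrd_band = "minor"
    else:
        hrd_band = "present"
    return EtiologySummary(
        uv_share=uv_share,
        uv_band="predominant" if uv_share >= uv_predominant_cutoff else "minor",
        apobec_flag=apobec >= apobec_cutoff,
        hrd_band=hrd_band,
    )
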