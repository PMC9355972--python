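"""Exposure refitting and per-mutation posterior signature assignment.

Given a region's 96-channel counts and a signature matrix H (rows h_v),
the exposure vector d estimates the mixing proportions of the signatures
in that region.  The default estimator is the multinomial maximum
likelihood mixture fit by expectation-maximization; non-negative least
squares on the normalized count vector is provided as an independent
cross-check route.

A mutation of channel i in region r is then assigned to the signature
maximizing the posterior

    P(signature v | channel i, region r) = h_vi * d_rv / sum_w h_wi * d_rw,

the argmax being its cognate signature.  Regions are the mutation
clusters by default; segment- and sample-level granularities are
available for comparison.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .catalog import MutationCatalog
from .clustering import BICClusterer
from .model import N_CHANNELS
from .segmentation import BICSegmenter
from .signatures import SignatureMatrix

_UNDERFLOW = 1e-300


def em_exposures(
    counts: np.ndarray,
    H: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    return_path: bool = False,
):
    """Multinomial mixture weight MLE by EM from uniform initialization.

    Channels with positive counts that every signature gives zero
    probability cannot be explained by the model; their counts are
    excluded from the fit and returned.

    Returns
    -------
    d : ndarray of shape (V,)
    excluded : float
        Total count mass excluded as unexplainable.
    path : list of float, optional
        Per-iteration log-likelihoods (when ``return_path``); the EM
        guarantee is that this sequence is non-decreasing.
    """
    c = np.asarray(counts, dtype=float)
    H = np.asarray(H, dtype=float)
    V = H.shape[0]
    explainable = H.sum(axis=0) > 0
    excluded = float(c[~explainable].sum())
    c = c * explainable
    n = c.sum()
    if n == 0:
        raise ValueError("no explainable counts to fit")
    d = np.full(V, 1.0 / V)
    path = []
    for _ in range(max_iter):
        mix = d @ H  # per-channel mixture probability
        if return_path:
            pos = c > 0
            path.append(float(np.dot(c[pos], np.log(mix[pos]))))
        # responsibilities-weighted counts, summed per signature
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(mix > 0, c / mix, 0.0)
        d_new = d * (H @ ratio) / n
        s = d_new.sum()
        if s <= 0:
            raise RuntimeError("EM degenerated to zero mass")
        d_new /= s
        if np.max(np.abs(d_new - d)) < tol:
            d = d_new
            break
        d = d_new
    if return_path:
        mix = d @ H
        pos = c > 0
        path.append(float(np.dot(c[pos], np.log(mix[pos]))))
        return d, excluded, path
    return d, excluded


def nnls_exposures(counts: np.ndarray, H: np.ndarray):
    """Non-negative least squares refit of the normalized count vector."""
    c = np.asarray(counts, dtype=float)
    H = np.asarray(H, dtype=float)
    explainable = H.sum(axis=0) > 0
    excluded = float(c[~explainable].sum())
    c = c * explainable
    n = c.sum()
    if n == 0:
        raise ValueError("no explainable counts to fit")
    w, _ = nnls(H.T, c / n)
    s = w.sum()
    if s <= 0:
        raise RuntimeError("NNLS returned an all-zero solution")
    return w / s, excluded


class ExposureEstimator(BaseEstimator):
    """Estimate signature exposures d for one or more count vectors.

    Parameters
    ----------
    signatures :
        The signature probability matrix H.
    method :
        ``"em"`` (default, multinomial MLE) or ``"nnls"``.
    min_exposure :
        Exposures below this proportion are zeroed and the vector
        renormalized (0 disables; 0.06 mimics the common
        refitting-tool discard rule).
    tol, max_iter :
        EM stopping rule: max absolute weight change below *tol* or
        *max_iter* iterations.

    Attributes
    ----------
    exposures_ : ndarray of shape (n_regions, V)
    excluded_counts_ : ndarray of shape (n_regions,)
        Count mass per region on channels no signature can produce.
    """

    def __init__(
        self,
        signatures: SignatureMatrix | None = None,
        method: str = "em",
        min_exposure: float = 0.0,
        tol: float = 1e-8,
        max_iter: int = 10_000,
    ):
        self.signatures = signatures
        self.method = method
        self.min_exposure = min_exposure
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y=None) -> "ExposureEstimator":
        if self.signatures is None:
            raise ValueError("signatures must be provided")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != N_CHANNELS:
            raise ValueError(f"count vectors must have {N_CHANNELS} channels")
        H = self.signatures.probs
        ds, excl = [], []
        for c in X:
            if self.method == "em":
                d, e = em_exposures(c, H, self.tol, self.max_iter)
            elif self.method == "nnls":
                d, e = nnls_exposures(c, H)
            else:
                raise ValueError(f"unknown method {self.method!r}")
            if self.min_exposure > 0:
                d = np.where(d >= self.min_exposure, d, 0.0)
                if d.sum() == 0:
                    raise RuntimeError("min_exposure removed every signature")
                d = d / d.sum()
            ds.append(d)
            excl.append(e)
        self.exposures_ = np.vstack(ds)
        self.excluded_counts_ = np.asarray(excl)
        return self

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).exposures_


def posterior_assign(
    channels: np.ndarray,
    region_labels: np.ndarray,
    exposures: np.ndarray,
    H: np.ndarray,
):
    """Per-mutation posterior over signatures and its argmax.

    Parameters
    ----------
    channels :
        Channel index per mutation.
    region_labels :
        Region (cluster) id per mutation, indexing rows of *exposures*.
    exposures :
        ``n_regions x V`` exposure matrix.
    H :
        ``V x 96`` signature matrix.

    Returns
    -------
    posterior : ndarray (n_mutations, V)
    argmax : ndarray (n_mutations,) of signature indices (ties to the
        lowest index)
    unassigned : ndarray (n_mutations,) bool; True where the posterior
        denominator underflows (no signature with positive exposure can
        produce the channel) — the row is left unnormalized-zero and no
        label is fabricated.
    """
    channels = np.asarray(channels)
    region_labels = np.asarray(region_labels)
    if channels.shape != region_labels.shape:
        raise ValueError("channels and region_labels differ in length")
    if (region_labels < 0).any():
        raise ValueError("mutation without a region: run segmentation/clustering first")
    exposures = np.asarray(exposures, dtype=float)
    H = np.asarray(H, dtype=float)
    n, V = len(channels), H.shape[0]
    posterior = np.zeros((n, V))
    argmax = np.zeros(n, dtype=np.int64)
    unassigned = np.zeros(n, dtype=bool)
    for r in np.unique(region_labels):
        mask = region_labels == r
        table = exposures[r][:, None] * H  # V x 96, joint weight
        denom = table.sum(axis=0)
        ch = channels[mask]
        den = denom[ch]
        bad = den < _UNDERFLOW
        post = np.zeros((mask.sum(), V))
        ok = ~bad
        post[ok] = table[:, ch[ok]].T / den[ok][:, None]
        posterior[mask] = post
        a = np.zeros(mask.sum(), dtype=np.int64)
        a[ok] = np.argmax(post[ok], axis=1)
        argmax[mask] = a
        u = unassigned[mask]
        u[bad] = True
        unassigned[mask] = u
    return posterior, argmax, unassigned


def assignment_accuracy(
    argmax: np.ndarray, truth: np.ndarray, unassigned: np.ndarray | None = None
) -> float:
    """Fraction of non-flagged mutations whose argmax matches the truth."""
    argmax = np.asarray(argmax)
    truth = np.asarray(truth)
    if argmax.shape != truth.shape:
        raise ValueError("assignment and truth lengths differ")
    if unassigned is None:
        unassigned = np.zeros(argmax.shape, dtype=bool)
    ok = ~np.asarray(unassigned)
    if ok.sum() == 0:
        return float("nan")
    return float(np.mean(argmax[ok] == truth[ok]))


class SignatureAssigner(BaseEstimator):
    """End-to-end estimator: segment, cluster, refit, assign.

    Parameters
    ----------
    signatures :
        Signature matrix H used for refitting and posteriors.
    lambda1, lambda2, min_bin_count :
        Segmentation/clustering tuning parameters (defaults 5, 5, 30).
    method :
        Exposure refit method, ``"em"`` or ``"nnls"``.
    granularity :
        Region definition for exposures: ``"cluster"`` (default),
        ``"segment"``, or ``"sample"``.
    min_exposure :
        Optional exposure discard threshold (see ExposureEstimator).

    Attributes
    ----------
    segmenter_ : BICSegmenter (granularity != "sample")
    clusterer_ : BICClusterer (granularity == "cluster")
    region_labels_ : ndarray, region id per mutation
    exposures_ : ndarray (n_regions, V)
    posterior_ : ndarray (n_mutations, V)
    labels_ : ndarray of signature indices per mutation
    signature_labels_ : list of signature id strings per mutation
    unassigned_ : ndarray of bool
    """

    def __init__(
        self,
        signatures: SignatureMatrix | None = None,
        lambda1: float = 5.0,
        lambda2: float = 5.0,
        min_bin_count: int = 30,
        method: str = "em",
        granularity: str = "cluster",
        min_exposure: float = 0.0,
    ):
        self.signatures = signatures
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.min_bin_count = min_bin_count
        self.method = method
        self.granularity = granularity
        self.min_exposure = min_exposure

    def fit(self, catalog: MutationCatalog, y=None) -> "SignatureAssigner":
        if self.signatures is None:
            raise ValueError("signatures must be provided")
        if self.granularity not in ("cluster", "segment", "sample"):
            raise ValueError(f"unknown granularity {self.granularity!r}")
        n = catalog.n
        if self.granularity == "sample":
            region = np.zeros(n, dtype=np.int64)
            ids = {s: i for i, s in enumerate(catalog.samples)}
            region[:] = catalog.df["sample_id"].map(ids).to_numpy()
        else:
            self.segmenter_ = BICSegmenter(
                lambda1=self.lambda1, min_bin_count=self.min_bin_count
            ).fit(catalog)
            if self.granularity == "segment":
                region = self.segmenter_.labels_
            else:
                self.clusterer_ = BICClusterer(lambda2=self.lambda2).fit(
                    self.segmenter_.segmentation_
                )
                region = self.clusterer_.clustering_.mutation_labels(
                    self.segmenter_.segmentation_, n
                )
        self.region_labels_ = region
        n_regions = int(region.max()) + 1
        counts = np.zeros((n_regions, N_CHANNELS))
        ch = catalog.channels()
        np.add.at(counts, (region, ch), 1.0)
        est = ExposureEstimator(
            signatures=self.signatures,
            method=self.method,
            min_exposure=self.min_exposure,
        ).fit(counts)
        self.exposure_estimator_ = est
        self.exposures_ = est.exposures_
        self.posterior_, self.labels_, self.unassigned_ = posterior_assign(
            ch, region, self.exposures_, self.signatures.probs
        )
        self.signature_labels_ = [
            None if u else self.signatures.signature_ids[v]
            for v, u in zip(self.labels_, self.unassigned_)
        ]
        return self

    def fit_predict(self, catalog: MutationCatalog, y=None) -> np.ndarray:
        return self.fit(catalog).labels_

    def score(self, catalog: MutationCatalog, truth: np.ndarray) -> float:
        """Assignment accuracy against true per-mutation signature indices."""
        check_is_fitted(self, "labels_")
        return assignment_accuracy(self.labels_, truth, self.unassigned_)
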