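"""Scikit-learn-style estimator wrapping the registration framework.

``FundusRegistrar`` follows the fit/transform contract: ``fit`` runs the
unsupervised training loop on a list of image pairs, ``transform`` warps
moving images onto their references with the trained model. Fitted state
lives in trailing-underscore attributes, and ``get_params`` /
``set_params`` (inherited from :class:`sklearn.base.BaseEstimator`) make
the class compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .corrnet import NetworkConfig, build_model, forward_grid
from .images import FundusImage, VesselMap
from .metrics import evaluate_all
from .pipeline import run_registration
from .stn import warp_vessel_map
from .train import TrainingConfig, train
from .preprocess import extract_structure_channel, to_working_resolution
from .vesselseg import segment_vessels

__all__ = ["FundusRegistrar"]


class FundusRegistrar(TransformerMixin, BaseEstimator):
    """Unsupervised deformable registration of fundus image pairs.

    Parameters
    ----------
    input_size : int
        Square working resolution (multiple of ``2**depth``).
    base_filters, depth, kernel_size : int
        Correspondence-network architecture.
    epochs, batch_size, learning_rate : training settings.
    refine_min_size : int
        Connected-component threshold applied to warped maps (0 = off).
    levels_used, threshold_fraction : vessel-segmentation settings.
    seed : int
        Controls weight initialization and shuffling.

    Attributes
    ----------
    model_ : RegistrationModel
        Trained correspondence network.
    learning_curve_ : list of float
        Mean NCC fitness per epoch.
    """

    def __init__(self, input_size: int = 512, base_filters: int = 16, depth: int = 2,
                 kernel_size: int = 3, epochs: int = 5000, batch_size: int = 8,
                 learning_rate: float = 1e-4, refine_min_size: int = 20,
                 levels_used: tuple[int, ...] = (2, 3), threshold_fraction: float = 0.15,
                 seed: int = 0):
        self.input_size = input_size
        self.base_filters = base_filters
        self.depth = depth
        self.kernel_size = kernel_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.refine_min_size = refine_min_size
        self.levels_used = levels_used
        self.threshold_fraction = threshold_fraction
        self.seed = seed

    # -- helpers -------------------------------------------------------
    def _segment(self, img: FundusImage) -> VesselMap:
        gray = extract_structure_channel(to_working_resolution(img, self.input_size))
        return segment_vessels(gray, levels_used=self.levels_used,
                               threshold_fraction=self.threshold_fraction)

    def _to_map_pair(self, pair) -> tuple[VesselMap, VesselMap]:
        a, b = pair
        if isinstance(a, FundusImage):
            return self._segment(a), self._segment(b)
        if isinstance(a, VesselMap):
            return a, b
        return VesselMap(soft=np.asarray(a, dtype=float)), VesselMap(soft=np.asarray(b, dtype=float))

    # -- sklearn surface ----------------------------------------------
    def fit(self, X, y=None):
        """Train on a list of (reference, moving) pairs.

        ``X`` may contain FundusImages, VesselMaps or bare [0, 1]
        arrays; ``y`` is ignored (the loop is unsupervised).
        """
        pairs = [self._to_map_pair(p) for p in X]
        config = NetworkConfig(base_filters=self.base_filters, depth=self.depth,
                               kernel_size=self.kernel_size, input_size=self.input_size)
        model = build_model(config, seed=self.seed)
        tconf = TrainingConfig(epochs=self.epochs, batch_size=self.batch_size,
                               learning_rate=self.learning_rate, seed=self.seed)
        self.model_, curve = train(model, pairs, tconf)
        self.learning_curve_ = curve
        return self

    def transform(self, X):
        """Warp each pair's moving map onto its reference.

        Returns a list of refined warped :class:`VesselMap` objects.
        """
        check_is_fitted(self, "model_")
        out = []
        for pair in X:
            b_ref, b_mov = self._to_map_pair(pair)
            disp = forward_grid(self.model_, b_ref, b_mov)
            warped = warp_vessel_map(b_mov, disp)
            if self.refine_min_size > 0:
                from .refine import cca_filter
                warped = cca_filter(warped, min_size=self.refine_min_size)
            out.append(warped)
        return out

    def register(self, i_ref: FundusImage, i_mov: FundusImage):
        """Full single-pair workflow; returns (b_warp, grid, report, composite)."""
        check_is_fitted(self, "model_")
        return run_registration(self.model_, i_ref, i_mov,
                                refine_min_size=self.refine_min_size,
                                levels_used=self.levels_used,
                                threshold_fraction=self.threshold_fraction)

    def score(self, X, y=None) -> float:
        """Mean Dice between warped and reference maps over the pairs."""
        check_is_fitted(self, "model_")
        warped = self.transform(X)
        dices = []
        for pair, w in zip(X, warped):
            b_ref, b_mov = self._to_map_pair(pair)
            dices.append(evaluate_all(b_ref, b_mov, w).dice)
        return float(np.mean(dices))
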