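"""scikit-learn style estimator wrapping the full pipeline.

``fit`` builds the metal-site template library from metal-bound structures;
``decision_function`` returns per-residue z-scores for a query and
``predict`` thresholds them into binding calls.  The class follows the
sklearn estimator contract (keyword-only constructor mirroring attributes,
``get_params``/``set_params``, fitted attributes with a trailing
underscore), so it composes with sklearn tooling such as ``clone``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import predict_eval as pe
from .scoring import ScoringParams
from .structure_io import ProteinStructure, read_pdb
from .template_library import TemplateLibrary, build_library


class FragmentTransformPredictor(BaseEstimator):
    """Metal ion-binding residue predictor (fragment transformation method).

    Parameters
    ----------
    cutoff : float
        Binding distance cutoff in Å (residues with an atom within this
        distance of an ion are site members).
    min_site_residues : int
        Minimum binding residues for a site to become a template.
    d_c : float
        Single-linkage threshold (Å) on the triplet-pair transformation
        distance.
    rmsd_max : float
        Cα-RMSD bound (Å) of the structure term; clusters at or above it
        are discarded.
    theta_seq : float
        Sequence-conservation threshold θ (s_seq must exceed it).
    combine_mode, aggregate_mode : str
        How the two conservation terms combine ("product" or "mean") and
        how qualifying clusters aggregate per residue ("sum" or "max").
    min_cluster_size : int
        Smallest aligned substructure kept.
    prefilter : bool
        Skip triplet pairs with negative BLOSUM62 score before clustering.
    thresholds : dict or None
        Per-metal z-score calling thresholds (defaults to the published
        per-metal values).
    exclude_source : bool
        Leave-one-out: skip templates from the query's own structure.
    """

    def __init__(
        self,
        cutoff: float = 3.5,
        min_site_residues: int = 3,
        d_c: float = 2.0,
        rmsd_max: float = 3.0,
        theta_seq: float = 0.30,
        combine_mode: str = "product",
        aggregate_mode: str = "sum",
        min_cluster_size: int = 3,
        prefilter: bool = False,
        thresholds: dict | None = None,
        exclude_source: bool = True,
    ):
        self.cutoff = cutoff
        self.min_site_residues = min_site_residues
        self.d_c = d_c
        self.rmsd_max = rmsd_max
        self.theta_seq = theta_seq
        self.combine_mode = combine_mode
        self.aggregate_mode = aggregate_mode
        self.min_cluster_size = min_cluster_size
        self.prefilter = prefilter
        self.thresholds = thresholds
        self.exclude_source = exclude_source

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _as_structures(X) -> list[ProteinStructure]:
        if isinstance(X, ProteinStructure):
            return [X]
        return [x if isinstance(x, ProteinStructure) else read_pdb(x) for x in X]

    def _params(self) -> ScoringParams:
        return ScoringParams(
            rmsd_max=self.rmsd_max,
            theta_seq=self.theta_seq,
            combine_mode=self.combine_mode,
            aggregate_mode=self.aggregate_mode,
            d_c=self.d_c,
            min_cluster_size=self.min_cluster_size,
            prefilter=self.prefilter,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "library_"):
            raise NotFittedError("call fit before predicting")

    # -- sklearn surface --------------------------------------------------
    def fit(self, X, y=None) -> "FragmentTransformPredictor":
        """Build the template library from metal-bound structures.

        ``X`` is a list of ProteinStructure objects or PDB paths; ``y`` is
        ignored (labels are the metal positions within the structures)."""
        structures = self._as_structures(X)
        self.library_: TemplateLibrary = build_library(
            structures, cutoff=self.cutoff, min_residues=self.min_site_residues
        )
        self.metals_ = sorted(self.library_.templates)
        self.n_templates_ = sum(self.library_.counts().values())
        return self

    def decision_function(self, X, metal: str) -> list[np.ndarray]:
        """Per-chain z-score vectors for each query structure."""
        self._check_fitted()
        out = []
        for structure in self._as_structures(X):
            pred = pe.predict(
                structure,
                self.library_,
                metal,
                params=self._params(),
                threshold=self._threshold(metal),
                exclude_source=self.exclude_source,
            )
            out.extend(cp.z for cp in pred.chains)
        return out

    def predict(self, X, metal: str) -> list[np.ndarray]:
        """Per-chain boolean binding calls for each query structure."""
        self._check_fitted()
        out = []
        for structure in self._as_structures(X):
            pred = pe.predict(
                structure,
                self.library_,
                metal,
                params=self._params(),
                threshold=self._threshold(metal),
                exclude_source=self.exclude_source,
            )
            out.extend(cp.calls for cp in pred.chains)
        return out

    def predict_result(self, structure, metal: str) -> pe.PredictionResult:
        """Full PredictionResult (refs, raw, z, calls) for one structure."""
        self._check_fitted()
        return pe.predict(
            self._as_structures(structure)[0],
            self.library_,
            metal,
            params=self._params(),
            threshold=self._threshold(metal),
            exclude_source=self.exclude_source,
        )

    def evaluate(self, X, target_fpr: float | None = None) -> pe.EvalReport:
        """Leave-one-out evaluation over a structure set."""
        self._check_fitted()
        return pe.evaluate_library(
            self.library_,
            self._as_structures(X),
            params=self._params(),
            thresholds=self.thresholds,
            target_fpr=target_fpr,
        )

    def _threshold(self, metal: str) -> float:
        table = self.thresholds or pe.DEFAULT_THRESHOLDS
        return table.get(metal.upper(), 2.0)
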