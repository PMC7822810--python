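"""Model/Results front end for the point-cloud hemodynamics surrogate.

Follows the fit/results convention of statistical modelling packages: a
:class:`HemodynamicPointNet` is constructed from a corpus (and optionally a
network configuration); ``fit()`` trains the network and returns a
:class:`SurrogateResults` carrying the trained weights, the loss trajectory,
per-region error diagnostics on the held-out models and a ``summary()``
table.  Prediction, clinical-index computation and persistence hang off the
results object.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import CorpusSplit, HemodynamicSample
from .evaluation import (
    ErrorReport,
    agreement,
    compute_ffr,
    graft_flow,
    regional_report,
)
from .exceptions import UserInputError
from .network import NetworkConfig, PointNetRegressor, TrainingResult, train_network

__all__ = ["HemodynamicPointNet", "SurrogateResults"]


class HemodynamicPointNet:
    """Surrogate model for one corpus (one op_state × field_kind).

    Parameters
    ----------
    corpus
        Train/test split of hemodynamic samples (all sharing field kind and
        operative state).
    config
        Network architecture and optimization settings; defaults to the
        package defaults (dual channel, shared trunk, 640-wide concat).
    """

    def __init__(self, corpus: CorpusSplit, config: NetworkConfig | None = None):
        self.corpus = corpus
        self.config = config or NetworkConfig()
        if not corpus.train:
            raise UserInputError("corpus has no training samples")
        self.field_kind = corpus.train[0].field_kind
        self.op_state = corpus.train[0].op_state

    @classmethod
    def from_corpus(cls, corpus: CorpusSplit, **config_kwargs) -> "HemodynamicPointNet":
        return cls(corpus, NetworkConfig(**config_kwargs))

    def fit(self, epochs: int | None = None) -> "SurrogateResults":
        """Train the network and evaluate it on the held-out models."""
        cfg = self.config
        if epochs is not None:
            cfg = dataclasses.replace(cfg, epochs=epochs)
        net = PointNetRegressor(cfg)
        tr = train_network(net, self.corpus, cfg)
        return SurrogateResults(self, tr)


class SurrogateResults:
    """Trained surrogate: weights, loss history, diagnostics, persistence."""

    def __init__(self, model: HemodynamicPointNet, training: TrainingResult):
        self.model = model
        self.training = training
        self.network = training.weights_handle
        self.loss_history = training.loss_history
        self._report: ErrorReport | None = None

    # -- prediction ---------------------------------------------------------

    def predict(self, sample: HemodynamicSample) -> np.ndarray:
        """N×3 predicted field at the sample's query coordinates."""
        return self.network.predict(sample.surface.coordinates, sample.query.coordinates)

    def predict_at(self, sample: HemodynamicSample, coordinates: np.ndarray) -> np.ndarray:
        """Predictions at arbitrary coordinates inside the sample's geometry."""
        return self.network.predict(sample.surface.coordinates, coordinates)

    # -- diagnostics --------------------------------------------------------

    def error_report(self, samples=None) -> ErrorReport:
        """Per-region NMAE/MRE over the test split (or given samples)."""
        if samples is None:
            if self._report is not None:
                return self._report
            samples = self.model.corpus.test
        preds = [self.predict(s) for s in samples]
        rep = regional_report(samples, preds)
        if samples is self.model.corpus.test:
            self._report = rep
        return rep

    def clinical_agreement(self, distal_offset: float = 0.03):
        """Pearson/Bland–Altman agreement of predicted vs reference clinical
        indices over the test split (FFR for pressure corpora, graft flow for
        postoperative velocity corpora)."""
        from .flow import solve_network

        samples = self.model.corpus.test
        ref, pred = [], []
        for s in samples:
            if s.tree is None:
                continue
            if self.model.field_kind == "pressure":
                sol = s.solution or solve_network(s.tree)
                ref.append(compute_ffr(s.tree, sol, distal_offset))
                pred.append(
                    compute_ffr(
                        s.tree,
                        lambda c, s=s: self.predict_at(s, c).mean(axis=1),
                        distal_offset,
                    )
                )
            elif s.op_state == "postoperative":
                ref.append(graft_flow(s.tree, s.solution))
                pred.append(
                    graft_flow(
                        s.tree, lambda c, s=s: self.network.predict(s.surface.coordinates, c)
                    )
                )
        if len(ref) < 3:
            raise UserInputError("need >= 3 test models with trees for agreement")
        return agreement(ref, pred)

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary (training run + per-region errors)."""
        cfg = self.training.config
        lines = [
            "Point-cloud hemodynamics surrogate".center(62),
            "=" * 62,
            f"{'field kind:':<22}{self.model.field_kind:>12}"
            f"{'  op state:':<16}{self.model.op_state:>12}",
            f"{'train models:':<22}{len(self.model.corpus.train):>12}"
            f"{'  test models:':<16}{len(self.model.corpus.test):>12}",
            f"{'epochs:':<22}{cfg.epochs:>12}"
            f"{'  parameters:':<16}{self.network.n_parameters:>12}",
            f"{'channels:':<22}"
            f"{('single' if cfg.single_channel else 'dual'):>12}"
            f"{'  shared trunk:':<16}{str(cfg.share_weights):>12}",
            f"{'initial MAE:':<22}"
            f"{(self.loss_history[0] if self.loss_history else float('nan')):>12.5g}"
            f"{'  final MAE:':<16}"
            f"{(self.loss_history[-1] if self.loss_history else float('nan')):>12.5g}",
            "-" * 62,
            f"{'region':<24}{'NMAE %':>18}{'MRE %':>18}",
        ]
        rep = self.error_report()
        for r in rep.regions:
            lines.append(
                f"{r:<24}"
                f"{rep.nmae_mean[r]:>9.2f} ± {rep.nmae_std[r]:<6.2f}"
                f"{rep.mre_mean[r]:>9.2f} ± {rep.mre_std[r]:<6.2f}"
            )
        lines.append("=" * 62)
        return "\n".join(lines)

    def save(self, path) -> None:
        self.network.save(path)

    @classmethod
    def load(cls, path, model: HemodynamicPointNet) -> "SurrogateResults":
        net = PointNetRegressor.load(path, model.config)
        tr = TrainingResult(
            weights_handle=net, loss_history=[], config=net.config,
            seed=net.config.seed, wall_time=0.0,
        )
        return cls(model, tr)
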