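"""Convolutional regression from methylation features to promoter activity.

``ConvPromoterRegressor`` is a scikit-learn style estimator: three
same-padded convolutional layers extract spatial methylation features
along the window axis (never mixing the two window scales), and two
fully connected layers map them to a single enrichment value per
promoter.  Separate models are trained per histone mark.

Transfer learning to a new sample domain freezes the convolutional
layers and continues training only the fully connected layers from
their pretrained weights, so one labeled sample suffices to recalibrate
the feature-to-activity mapping.  Cohort predictions can be averaged
over an ensemble of transferred models, optionally leaving out the
model transferred on the sample being predicted.
"""

from __future__ import annotations

import copy

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .nn import ConvNet, train_network


def _as_array(X) -> np.ndarray:
    values = getattr(X, "values", X)
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 4:
        raise ValueError(f"expected a 4-d feature tensor, got shape {arr.shape}")
    return arr


class ConvPromoterRegressor(RegressorMixin, BaseEstimator):
    """Predict per-promoter histone-mark enrichment from feature tensors.

    Parameters
    ----------
    conv_filters : tuple of int
        Filters per convolutional layer; ``()`` gives the two-layer
        fully connected baseline.
    kernel_size : int
        Convolution width along the window axis (height is always 1).
    fc_hidden : int
        Hidden units in the first fully connected layer.
    leaky_slope : float
        Negative-side slope of the leaky rectifier.
    max_norm : float
        Max L2 norm of each unit's incoming weight vector, enforced
        after every update.
    batch_size, max_epochs, patience, min_delta, validation_fraction
        Training protocol: mini-batch MSE with Adadelta, an internal
        shuffled train/validation split, and early stopping restoring
        the best validation weights.
    random_state : int or None
        Seed for weight initialization and shuffling; identical seeds
        give identical fitted weights (single-threaded).
    """

    def __init__(
        self,
        conv_filters=(64, 64, 32),
        kernel_size=3,
        fc_hidden=128,
        leaky_slope=0.1,
        max_norm=3.0,
        batch_size=64,
        max_epochs=80,
        patience=10,
        min_delta=1e-4,
        validation_fraction=0.2,
        random_state=None,
    ):
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.fc_hidden = fc_hidden
        self.leaky_slope = leaky_slope
        self.max_norm = max_norm
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _build(self, input_shape, rng) -> ConvNet:
        return ConvNet(
            input_shape=input_shape,
            conv_filters=tuple(self.conv_filters),
            kernel_size=self.kernel_size,
            fc_hidden=self.fc_hidden,
            leaky_slope=self.leaky_slope,
            max_norm=self.max_norm,
            rng=rng,
        )

    def fit(self, X, y, sample_ids=None):
        """Train on pooled promoter rows.

        ``X`` may be one tensor of shape (n, scales, windows, channels)
        or a list of per-sample tensors; ``y`` correspondingly one vector
        or a list of vectors.  Rows from all samples are concatenated and
        shuffled before the train/validation split.
        """
        X, y = self._pool(X, y)
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build(X.shape[1:], rng)
        self.history_ = train_network(
            self.net_, X, y, rng,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            min_delta=self.min_delta,
            validation_fraction=self.validation_fraction,
        )
        self.n_epochs_ = self.history_["n_epochs"]
        self.input_shape_ = X.shape[1:]
        self.source_sample_ids_ = list(sample_ids) if sample_ids is not None else None
        self.frozen_convs_ = False
        self.transfer_sample_id_ = None
        return self

    @staticmethod
    def _pool(X, y):
        if isinstance(X, (list, tuple)):
            X = np.concatenate([_as_array(x) for x in X], axis=0)
            y = np.concatenate([np.asarray(v, dtype=float) for v in y])
        else:
            X = _as_array(X)
            y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("features and response are not aligned")
        return X, y

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = _as_array(X)
        preds = []
        # chunked forward pass to bound memory on large catalogs
        for start in range(0, X.shape[0], 4096):
            preds.append(self.net_.forward(X[start:start + 4096]))
        return np.concatenate(preds) if preds else np.empty(0)

    def transfer(self, X, y, sample_id=None, reinit_fc=False):
        """Domain-adapt to one labeled sample with frozen conv layers.

        Returns a new fitted estimator whose convolutional weights are
        bit-identical to this model's and whose fully connected layers
        were retrained starting from the pretrained weights (or from a
        fresh initialization with ``reinit_fc=True``).
        """
        check_is_fitted(self, "net_")
        X, y = self._pool(X, y)
        if X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"transfer tensor shape {X.shape[1:]} does not match model input {self.input_shape_}"
            )
        new = copy.deepcopy(self)
        rng = np.random.default_rng(self.random_state)
        if reinit_fc:
            fresh = self._build(self.input_shape_, rng)
            new.net_.fc1 = fresh.fc1
            new.net_.fc2 = fresh.fc2
        new.net_.freeze_convs()
        new.history_ = train_network(
            new.net_, X, y, rng,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            min_delta=self.min_delta,
            validation_fraction=self.validation_fraction,
        )
        new.n_epochs_ = new.history_["n_epochs"]
        new.frozen_convs_ = True
        new.transfer_sample_id_ = sample_id
        return new

    def conv_weights(self) -> list[np.ndarray]:
        check_is_fitted(self, "net_")
        out = []
        for layer in self.net_.convs:
            out.extend([layer.W.copy(), layer.b.copy()])
        return out

    def n_parameters(self) -> int:
        check_is_fitted(self, "net_")
        return self.net_.n_parameters()


def save_model(model: ConvPromoterRegressor, directory) -> None:
    """Persist weights (npz) plus architecture/metadata (JSON) in one directory."""
    import json
    from pathlib import Path

    check_is_fitted(model, "net_")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    weights = model.net_.get_weights()
    np.savez_compressed(directory / "weights.npz", **{f"w{i}": w for i, w in enumerate(weights)})
    meta = {
        "params": model.get_params(),
        "input_shape": list(model.input_shape_),
        "n_epochs": model.n_epochs_,
        "frozen_convs": model.frozen_convs_,
        "transfer_sample_id": model.transfer_sample_id_,
        "source_sample_ids": model.source_sample_ids_,
        "final_val_loss": model.history_.get("best_val_loss"),
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2, default=str))


def load_model(directory) -> ConvPromoterRegressor:
    import json
    from pathlib import Path

    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    params = dict(meta["params"])
    if isinstance(params.get("conv_filters"), list):
        params["conv_filters"] = tuple(params["conv_filters"])
    model = ConvPromoterRegressor(**params)
    rng = np.random.default_rng(model.random_state)
    model.input_shape_ = tuple(meta["input_shape"])
    model.net_ = model._build(model.input_shape_, rng)
    data = np.load(directory / "weights.npz")
    model.net_.set_weights([data[f"w{i}"] for i in range(len(data.files))])
    model.n_epochs_ = meta.get("n_epochs", 0)
    model.frozen_convs_ = meta.get("frozen_convs", False)
    model.transfer_sample_id_ = meta.get("transfer_sample_id")
    model.source_sample_ids_ = meta.get("source_sample_ids")
    model.history_ = {"best_val_loss": meta.get("final_val_loss")}
    return model


def ensemble_predict(models, X, exclude_sample=None) -> np.ndarray:
    """Arithmetic mean of member predictions, optionally leave-one-out.

    A model whose ``transfer_sample_id_`` equals ``exclude_sample`` is
    omitted, so a sample is never predicted by the model transferred on
    itself.
    """
    members = [
        m for m in models
        if exclude_sample is None or getattr(m, "transfer_sample_id_", None) != exclude_sample
    ]
    if not members:
        raise ValueError("no models left in the ensemble after exclusion")
    preds = np.stack([m.predict(X) for m in members], axis=0)
    return preds.mean(axis=0)


def select_transfer_samples(expression_by_sample, activity_by_sample, gene_map,
                            threshold: float = 0.60) -> list:
    """Choose samples whose gene expression is consistent with activity.

    For each sample, promoter activity is aggregated to genes (max over
    a gene's promoters), compared with log-scaled FPKM, and the sample
    is kept when the squared Pearson correlation is at least
    ``threshold``.  Guards transfer learning against samples whose
    ChIP-seq labels are unreliable.
    """
    from .activity import expression_consistency

    selected = []
    for sample_id, activity in activity_by_sample.items():
        expr = expression_by_sample[sample_id]
        stats = expression_consistency(activity, expr, gene_map)
        if stats["r2"] >= threshold:
            selected.append(sample_id)
    return selected
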