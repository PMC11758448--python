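"""High-level modelling surface: a Model built from data, fit() -> Results.

``MaterialDecompositionGAN`` bundles a cohort of paired cases with the
architecture and training protocol; ``fit()`` runs the adversarial loop and
returns a :class:`DecompositionGANResults` carrying the trained networks,
the loss/weight history, and evaluation helpers (image-quality scoring and
automated dual-energy reading of the generated maps).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import quality as _quality
from .model import (Discriminator, Generator, ModelConfig, PairedPrediction,
                    load_checkpoint, save_checkpoint)
from .phantom import PairedCase, classify_by_decomposition, decomposition_score
from .training import TrainConfig, train

__all__ = ["MaterialDecompositionGAN", "DecompositionGANResults"]


class MaterialDecompositionGAN:
    """Two-decoder transformer GAN translating SECT into (sVNC, sIOM).

    Parameters
    ----------
    cases : list of PairedCase
        Training cohort of matched (SECT, VNC, IOM) triplets.
    model_config, train_config : optional
        Architecture and protocol; defaults are the 2D desk-scale setup.
    """

    def __init__(self, cases: list[PairedCase],
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        if not cases:
            raise ValueError("cases must be a nonempty list of PairedCase")
        self.cases = list(cases)
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        shape = cases[0].shape
        self.model_config.validate_input_shape(
            self.train_config.crop_size or shape)

    def fit(self, callback=None) -> "DecompositionGANResults":
        """Train generator and discriminators; returns a Results object."""
        gen = Generator(self.model_config, seed=self.train_config.seed)
        disc_shape = self.train_config.crop_size or self.cases[0].shape
        disc_vnc = disc_iom = None
        if self.train_config.adversarial:
            disc_vnc = Discriminator(self.model_config, disc_shape,
                                     seed=self.train_config.seed + 1)
            disc_iom = Discriminator(self.model_config, disc_shape,
                                     seed=self.train_config.seed + 2)
        history = train(self.cases, gen, disc_vnc, disc_iom,
                        self.train_config, callback=callback)
        return DecompositionGANResults(self, gen, disc_vnc, disc_iom, history)


class DecompositionGANResults:
    """Fitted generator plus training history and evaluation helpers."""

    def __init__(self, model: MaterialDecompositionGAN | None,
                 generator: Generator,
                 disc_vnc: Discriminator | None,
                 disc_iom: Discriminator | None,
                 history: pd.DataFrame):
        self.model = model
        self.generator = generator
        self.disc_vnc = disc_vnc
        self.disc_iom = disc_iom
        self.history = history

    # -- inference ------------------------------------------------------------
    def predict(self, sect: np.ndarray | PairedCase,
                case_id: str = "") -> PairedPrediction:
        if isinstance(sect, PairedCase):
            return self.generator.generate(sect.sect, case_id=sect.case_id)
        return self.generator.generate(np.asarray(sect), case_id=case_id)

    def predict_cases(self, cases: list[PairedCase]) -> list[PairedPrediction]:
        return [self.predict(c) for c in cases]

    # -- evaluation -----------------------------------------------------------
    def evaluate(self, cases: list[PairedCase]) -> _quality.QualityReport:
        """PSNR/SSIM of generated maps against ground truth."""
        return _quality.evaluate_pairs(self.predict_cases(cases), cases)

    def read_cases(self, cases: list[PairedCase],
                   threshold: float = 20.0) -> pd.DataFrame:
        """Automated dual-energy reading of the generated maps.

        Applies the decomposition rule (persistent VNC elevation => blood)
        to each generated (sVNC, sIOM) pair; also records the continuous
        elevation score for ROC analysis and the ground-truth label.
        """
        rows = []
        for case in cases:
            pred = self.predict(case)
            call = classify_by_decomposition(pred.svnc, pred.siom,
                                             case.lesion_mask, threshold)
            rows.append({"case_id": case.case_id,
                         "call": call,
                         "score": decomposition_score(pred.svnc,
                                                      case.lesion_mask),
                         "gold": case.case_label})
        return pd.DataFrame(rows)

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        h = self.history
        lines = [
            "Material-decomposition GAN fit",
            "=" * 46,
            f"generator parameters:      {self.generator.n_parameters():>10d}",
        ]
        if self.disc_vnc is not None:
            lines.append(f"discriminator parameters:  "
                         f"{self.disc_vnc.n_parameters():>10d}  (x2)")
        lines += [
            f"iterations:                {len(h):>10d}",
            f"final L1 (VNC):            {h.l1_vnc.iloc[-1]:>10.3f}",
            f"final L1 (IOM):            {h.l1_iom.iloc[-1]:>10.3f}",
            f"final task weights:        ({h.w_vnc.iloc[-1]:.3f}, "
            f"{h.w_iom.iloc[-1]:.3f})",
            f"final learning rate:       {h.lr.iloc[-1]:>10.2e}",
        ]
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        save_checkpoint(path, self.generator, self.disc_vnc, self.disc_iom)
        self.history.to_csv(Path(path).with_suffix(".history.csv"), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "DecompositionGANResults":
        gen, dv, di, _ = load_checkpoint(path)
        hist_path = Path(path).with_suffix(".history.csv")
        history = (pd.read_csv(hist_path) if hist_path.exists()
                   else pd.DataFrame())
        return cls(None, gen, dv, di, history)
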