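"""Plain SGD with classical momentum."""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np


class SGD:
    def __init__(self, parameters: List[Tuple[str, np.ndarray]],
                 momentum: float = 0.95) -> None:
        self.parameters = parameters
        self.momentum = momentum
        self.velocity: Dict[str, np.ndarray] = {
            name: np.zeros_like(p) for name, p in parameters}

    def step(self, grads: Dict[str, np.ndarray], lr: float) -> None:
        for name, p in self.parameters:
            v = self.velocity[name]
            v *= self.momentum
            v -= lr * grads[name]
            p += v
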