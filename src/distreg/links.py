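"""Link functions mapping distribution-parameter domains to the real line.

Each distribution parameter theta is modeled through eta = g(theta), where
eta is an unconstrained additive predictor.  ``inverse`` maps the predictor
back to the parameter scale and ``dinverse`` is d theta / d eta, needed for
likelihood gradients.
"""

from __future__ import annotations

import numpy as np

# predictor clipping bound for exp/expit links; exp(+-35) spans ~1e-16..1e15
_ETA_MAX = 35.0


class Link:
    name: str = "abstract"

    def __call__(self, theta):
        raise NotImplementedError

    def inverse(self, eta):
        raise NotImplementedError

    def dinverse(self, eta):
        """Derivative of the inverse link, d theta / d eta."""
        raise NotImplementedError

    def __repr__(self):  # pragma: no cover
        return f"{type(self).__name__}()"


class IdentityLink(Link):
    name = "identity"

    def __call__(self, theta):
        return np.asarray(theta, dtype=float)

    def inverse(self, eta):
        return np.asarray(eta, dtype=float)

    def dinverse(self, eta):
        return np.ones_like(np.asarray(eta, dtype=float))


class LogLink(Link):
    name = "log"

    def __call__(self, theta):
        return np.log(theta)

    def inverse(self, eta):
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    def dinverse(self, eta):
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))


class LogitLink(Link):
    name = "logit"

    def __call__(self, theta):
        theta = np.asarray(theta, dtype=float)
        return np.log(theta / (1.0 - theta))

    def inverse(self, eta):
        eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
        return 1.0 / (1.0 + np.exp(-eta))

    def dinverse(self, eta):
        p = self.inverse(eta)
        return p * (1.0 - p)


_LINKS = {
    "identity": IdentityLink(),
    "log": LogLink(),
    "logit": LogitLink(),
}


def get_link(name) -> Link:
    """Resolve a link by name; Link instances pass through."""
    if isinstance(name, Link):
        return name
    try:
        return _LINKS[name]
    except KeyError:
        raise ValueError(
            f"unknown link {name!r}; available: {sorted(_LINKS)}"
        ) from None
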