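"""Reference parameter sets ("Hubble parameters").

Maximum-likelihood parameters for each agent, fitted in the source study to
the first 21 all-pairs test trials of a rhesus monkey ("Hubble") performing
a 7-item transitive-inference task.  They are shipped as constants: the
behavioral dataset itself is not public, so these values are inputs to the
simulations, not quantities this package re-estimates.
"""

from types import MappingProxyType

__all__ = ["HUBBLE_PARAMETERS"]

HUBBLE_PARAMETERS = MappingProxyType(
    {
        "q": MappingProxyType({"delta": 0.138, "theta": 2.280, "gamma": 0.373}),
        "vtm": MappingProxyType({"delta": 0.137, "theta": 2.260, "tau": 0.406}),
        "remerge": MappingProxyType(
            {"lam": 2.690, "omega": 15.0, "theta": 4.971, "delta": 0.500}
        ),
        "elo": MappingProxyType({"delta": 0.079, "theta": 1.529}),
        "smc": MappingProxyType({"sigma0": 0.5, "sigma": 0.032, "theta": 1.410}),
        "betasort": MappingProxyType({"rho": 0.188, "phi": 0.495}),
    }
)
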