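"""Optional interaction plots (raw and dose-effect-removed views)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .interaction import DoseResponse, InteractionResult, ReferenceModel


def plot_interaction(
    dr: DoseResponse,
    ref: ReferenceModel,
    res: InteractionResult,
    path: str | Path,
) -> None:
    """Two-panel per-strain plot: raw L vs dose against the reference band
    (left) and the dose-effect-removed interaction with its quadratic fit
    (right)."""
    fig, (ax_raw, ax_adj) = plt.subplots(1, 2, figsize=(9, 4), sharex=True)

    ax_raw.fill_between(ref.doses, ref.band_low, ref.band_high, alpha=0.3,
                        color="gray", label="reference central 95%")
    ax_raw.plot(ref.doses, ref.central, "k--", label="reference median")
    ax_raw.plot(dr.doses, dr.L_values, "o-", label=dr.strain_id)
    ax_raw.set_xlabel("oligomycin (ug/mL)")
    ax_raw.set_ylabel("L (h)")
    ax_raw.legend(fontsize=8)

    ax_adj.axhline(0.0, color="gray", lw=0.8)
    ax_adj.plot(dr.doses, res.L_adj, "o", label="adjusted response")
    if not (res.A != res.A):  # A is finite when the quadratic was fit
        d = ref.doses
        ax_adj.plot(d, res.A + res.B * d + res.C * d * d, "-",
                    label=f"quadratic (INT={res.INT:.1f} h)")
    ax_adj.set_xlabel("oligomycin (ug/mL)")
    ax_adj.set_ylabel("interaction L (h)")
    ax_adj.legend(fontsize=8)

    fig.suptitle(f"{dr.strain_id}: tier {res.tier}, {res.interaction_class}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
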