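"""Published reference tables for worked examples and cross-checks.

Small published summary tables from a stereological survey of
pSer202 tau-immunoreactive pathology in the cerebral cortex of three
muskoxen (an old male, a middle-aged female and an old female) with a
human chronic-traumatic-encephalopathy (CTE) comparison case.  These
are analysis *outputs* transcribed at their printed precision; they are
useful as inputs to the comparison utilities (density ratio tables,
vessel-association worked examples), not as fixtures for the estimators
themselves.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["muskox_layer_densities", "muskox_vessel_association"]

_LAYER_DENSITIES_CSV = """\
subject_id,region,layer,structure,density_value,unit_scale
old_male,prefrontal,I,neuropil_thread,26.38,per_cm3
old_male,prefrontal,I,neuritic_thread_cluster,5.05,per_cm3
old_male,prefrontal,I,neuron,0.04,per_cm3
old_male,prefrontal,II,neuropil_thread,24.15,per_cm3
old_male,prefrontal,II,neuritic_thread_cluster,4.66,per_cm3
old_male,prefrontal,II,neuron,0.35,per_cm3
old_male,prefrontal,III,neuropil_thread,12.81,per_cm3
old_male,prefrontal,III,neuritic_thread_cluster,2.01,per_cm3
old_male,prefrontal,III,neuron,0.09,per_cm3
old_male,prefrontal,IV-VI,neuropil_thread,15.26,per_cm3
old_male,prefrontal,IV-VI,neuritic_thread_cluster,0.83,per_cm3
old_male,prefrontal,IV-VI,neuron,0.19,per_cm3
old_male,prefrontal,WM,neuropil_thread,2.58,per_cm3
old_male,prefrontal,WM,neuritic_thread_cluster,0.14,per_cm3
old_male,prefrontal,WM,neuron,0.02,per_cm3
old_male,parietal,I,neuropil_thread,46.56,per_cm3
old_male,parietal,I,neuritic_thread_cluster,0.16,per_cm3
old_male,parietal,I,neuron,0.0,per_cm3
old_male,parietal,II,neuropil_thread,31.58,per_cm3
old_male,parietal,II,neuritic_thread_cluster,0.95,per_cm3
old_male,parietal,II,neuron,0.0,per_cm3
old_male,parietal,III,neuropil_thread,15.74,per_cm3
old_male,parietal,III,neuritic_thread_cluster,0.81,per_cm3
old_male,parietal,III,neuron,0.0,per_cm3
old_male,parietal,IV-VI,neuropil_thread,13.72,per_cm3
old_male,parietal,IV-VI,neuritic_thread_cluster,0.48,per_cm3
old_male,parietal,IV-VI,neuron,0.1,per_cm3
old_male,parietal,WM,neuropil_thread,2.67,per_cm3
old_male,parietal,WM,neuritic_thread_cluster,0.0,per_cm3
old_male,parietal,WM,neuron,0.0,per_cm3
middle_aged_female,prefrontal,I,neuropil_thread,838.06,per_cm3
middle_aged_female,prefrontal,I,neuritic_thread_cluster,102.55,per_cm3
middle_aged_female,prefrontal,I,neuron,0.3,per_cm3
middle_aged_female,prefrontal,II,neuropil_thread,606.09,per_cm3
middle_aged_female,prefrontal,II,neuritic_thread_cluster,76.88,per_cm3
middle_aged_female,prefrontal,II,neuron,5.06,per_cm3
middle_aged_female,prefrontal,III,neuropil_thread,386.74,per_cm3
middle_aged_female,prefrontal,III,neuritic_thread_cluster,46.31,per_cm3
middle_aged_female,prefrontal,III,neuron,1.56,per_cm3
middle_aged_female,prefrontal,IV-VI,neuropil_thread,310.93,per_cm3
middle_aged_female,prefrontal,IV-VI,neuritic_thread_cluster,36.71,per_cm3
middle_aged_female,prefrontal,IV-VI,neuron,1.66,per_cm3
middle_aged_female,prefrontal,WM,neuropil_thread,84.21,per_cm3
middle_aged_female,prefrontal,WM,neuritic_thread_cluster,7.8,per_cm3
middle_aged_female,prefrontal,WM,neuron,0.0,per_cm3
middle_aged_female,parietal,I,neuropil_thread,68.31,per_cm3
middle_aged_female,parietal,I,neuritic_thread_cluster,0.82,per_cm3
middle_aged_female,parietal,I,neuron,0.0,per_cm3
middle_aged_female,parietal,II,neuropil_thread,31.34,per_cm3
middle_aged_female,parietal,II,neuritic_thread_cluster,0.72,per_cm3
middle_aged_female,parietal,II,neuron,0.18,per_cm3
middle_aged_female,parietal,III,neuropil_thread,19.11,per_cm3
middle_aged_female,parietal,III,neuritic_thread_cluster,0.54,per_cm3
middle_aged_female,parietal,III,neuron,0.0,per_cm3
middle_aged_female,parietal,IV-VI,neuropil_thread,24.9,per_cm3
middle_aged_female,parietal,IV-VI,neuritic_thread_cluster,0.39,per_cm3
middle_aged_female,parietal,IV-VI,neuron,0.0,per_cm3
middle_aged_female,parietal,WM,neuropil_thread,3.81,per_cm3
middle_aged_female,parietal,WM,neuritic_thread_cluster,0.04,per_cm3
middle_aged_female,parietal,WM,neuron,0.0,per_cm3
old_female,prefrontal,I,neuropil_thread,14345.69,per_cm3
old_female,prefrontal,I,neuritic_thread_cluster,380.7,per_cm3
old_female,prefrontal,I,neuron,0.0,per_cm3
old_female,prefrontal,II,neuropil_thread,9049.63,per_cm3
old_female,prefrontal,II,neuritic_thread_cluster,856.97,per_cm3
old_female,prefrontal,II,neuron,0.0,per_cm3
old_female,prefrontal,III,neuropil_thread,6385.27,per_cm3
old_female,prefrontal,III,neuritic_thread_cluster,349.36,per_cm3
old_female,prefrontal,III,neuron,6.24,per_cm3
old_female,prefrontal,IV-VI,neuropil_thread,6306.02,per_cm3
old_female,prefrontal,IV-VI,neuritic_thread_cluster,292.55,per_cm3
old_female,prefrontal,IV-VI,neuron,24.38,per_cm3
old_female,prefrontal,WM,neuropil_thread,1428.7,per_cm3
old_female,prefrontal,WM,neuritic_thread_cluster,191.0,per_cm3
old_female,prefrontal,WM,neuron,0.0,per_cm3
old_female,parietal,I,neuropil_thread,164.73,per_cm3
old_female,parietal,I,neuritic_thread_cluster,6.13,per_cm3
old_female,parietal,I,neuron,0.0,per_cm3
old_female,parietal,II,neuropil_thread,239.71,per_cm3
old_female,parietal,II,neuritic_thread_cluster,12.51,per_cm3
old_female,parietal,II,neuron,0.48,per_cm3
old_female,parietal,III,neuropil_thread,74.79,per_cm3
old_female,parietal,III,neuritic_thread_cluster,3.58,per_cm3
old_female,parietal,III,neuron,0.05,per_cm3
old_female,parietal,IV-VI,neuropil_thread,27.55,per_cm3
old_female,parietal,IV-VI,neuritic_thread_cluster,2.02,per_cm3
old_female,parietal,IV-VI,neuron,0.0,per_cm3
old_female,parietal,WM,neuropil_thread,7.81,per_cm3
old_female,parietal,WM,neuritic_thread_cluster,0.14,per_cm3
old_female,parietal,WM,neuron,0.07,per_cm3
"""

_VESSEL_CSV = """\
subject_id,total_vessels,tau_associated_vessels,pct_associated,mean_distance_um
old_male,190,8,4.07,70.8
middle_aged_female,202,9,4.5,54.4
old_female,260,60,23.1,41.0
cte_human,94,58,61.7,29.9
"""


def muskox_layer_densities() -> pd.DataFrame:
    """Published layer-wise densities (estimated population per cm³).

    Long-format table: subject × region × layer × structure, densities
    at their printed precision.  Note the old-female prefrontal
    white-matter row is transcribed from a typographically ambiguous
    source cell; its values should not anchor any quantitative check.
    """
    return pd.read_csv(io.StringIO(_LAYER_DENSITIES_CSV))


def muskox_vessel_association() -> pd.DataFrame:
    """Published perivascular association summary (one section each).

    Vessels larger than 30 µm in diameter counted exhaustively; a vessel
    is tau-associated when a pSer202 tau-immunoreactive structure lies
    within 100 µm of its edge.  The printed old-male percentage (4.07%)
    is not consistent with its own counts (8/190 = 4.21%); the table is
    reproduced as printed and the inconsistency is left to the caller.
    """
    return pd.read_csv(io.StringIO(_VESSEL_CSV))
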