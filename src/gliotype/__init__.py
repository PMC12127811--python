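"""gliotype: multi-modal MRI glioma genotyping (IDH, ATRX, 1p/19q).

A dual-path 3-D convolutional front end with transformer and dual-attention
branches, an inter-gene-relationship classifier head, and an imbalance-aware
multi-task loss, exercised end-to-end on synthetic MRI phantom cohorts.
"""

__version__ = "0.1.0"

__all__ = ["GliomaGenotypeClassifier", "__version__"]


def __getattr__(name):
    # lazy import keeps `import gliotype` light for CLI --help and submodule use
    if name == "GliomaGenotypeClassifier":
        from .estimator import GliomaGenotypeClassifier

        return GliomaGenotypeClassifier
    raise AttributeError(name)
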