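"""limbicnet: restoration, limbic cropping, 3-D CNN classification, and
class-activation-map explainability for FDG-PET-like volumes, with a
synthetic phantom-cohort generator standing in for clinical data."""

from importlib import resources

from .volume import AtlasVolume, Volume
from .phantoms import (CohortSpec, ScannerProfile, build_atlas, degrade,
                       generate_cohort, make_phantom)
from .restoration import (MMWFConfig, PSFKernel, RestorationConfig,
                          TVDeblurConfig, make_psf, mmwf_denoise,
                          mmwf_window_stats, restore_volume, tv_l1_deblur,
                          tv_objective)
from .cropping import CropBox, crop, embed, limbic_crop_box
from .evaluation import (ConfusionCounts, MetricSet, confusion,
                         cross_validate, metrics, split_train_test)
from .cam import ActivationMap, RegionImportance, average_maps, cam, region_importance
from .nn import (ModelConfig, TrainedModel, build_model, layer_shapes,
                 predict, train)
from .pipeline import (Condition, ExperimentConfig, run_benchmark,
                       run_experiment, validate_config)

__version__ = "0.1.0"


def default_config_path() -> str:
    """Path to the shipped 10-condition experiment config."""
    return str(resources.files("limbicnet").joinpath("configs/default.yaml"))
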