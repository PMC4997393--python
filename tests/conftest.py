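import pytest

from bopmap.model import BrandedItem, GenericFood, NutrientPanel


def make_panel(**kwargs) -> NutrientPanel:
    micros = kwargs.pop("micronutrients", {})
    return NutrientPanel(micronutrients=dict(micros), **kwargs)


def make_branded(item_id="B1", description="test item", group="snacks",
                 **panel_kwargs) -> BrandedItem:
    return BrandedItem(item_id=item_id, description=description,
                       food_group=group, panel=make_panel(**panel_kwargs))


def make_generic(code="G1", description="generic item", group="snacks",
                 energy_kcal=100.0, fat_g=10.0, protein_g=5.0, carb_g=20.0,
                 **panel_kwargs) -> GenericFood:
    return GenericFood(code=code, description=description, food_group=group,
                       panel=make_panel(energy_kcal=energy_kcal, fat_g=fat_g,
                                        protein_g=protein_g, carb_g=carb_g,
                                        **panel_kwargs))


@pytest.fixture
def small_generics() -> list[GenericFood]:
    """Five well-separated reference foods across two groups."""
    return [
        make_generic("G_BEER", "beer, lager", "alcoholic drinks",
                     energy_kcal=40, fat_g=0.1, protein_g=0.3, carb_g=3.0,
                     sugars_g=2.0, micronutrients={"iron_mg": 0.02}),
        make_generic("G_COLA", "cola, carbonated drink", "soft drinks",
                     energy_kcal=42, fat_g=0.1, protein_g=0.1, carb_g=10.6,
                     sugars_g=10.6, micronutrients={"iron_mg": 0.01}),
        make_generic("G_BREAD", "bread, white, sliced", "bread",
                     energy_kcal=235, fat_g=1.9, protein_g=8.4, carb_g=49.3,
                     fibre_g=2.5, micronutrients={"iron_mg": 1.6,
                                                  "calcium_mg": 110.0}),
        make_generic("G_CHEESE", "cheese, cheddar", "dairy",
                     energy_kcal=416, fat_g=34.9, protein_g=25.4, carb_g=0.1,
                     satfat_g=21.7, micronutrients={"calcium_mg": 739.0}),
        make_generic("G_FISH", "fish, cod, breaded", "fish",
                     energy_kcal=200, fat_g=10.0, protein_g=13.0, carb_g=15.0,
                     micronutrients={"iron_mg": 0.5}),
    ]
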