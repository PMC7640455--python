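# Mapping from the 13 survey 24-h recall food items to the 7 reachable
# child-dietary-diversity food groups.  The recall instrument has no item
# for "foods cooked in oil or fat", so that eighth group is never scored
# and the attainable score range is 0-7.
class_labels:
  1: grains_roots_tubers
  2: vitamin_a_rich
  3: other_fruits_vegetables
  4: meat_poultry_fish
  5: eggs
  6: pulses_legumes_nuts
  7: milk_products
items:
  bread_noodles: 1
  potato_cassava: 1
  eggs: 5
  meat: 4
  orange_vegetables: 2
  dark_green_leafy_vegetables: 3
  orange_fruits: 2
  other_fruits: 3
  organ_meat: 4
  fish_shellfish: 4
  beans_peas_lentils: 6
  milk_products: 7
  insects: 4
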