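brand,sector,pct_permitted
Sanitarium,packaged_food,23
Anchor,packaged_food,50
Fresh'n Fruity,packaged_food,50
Meadow Fresh,packaged_food,60
Domino's Pizza,fast_food,2
St Pierre's Sushi,fast_food,70
Hell Pizza,fast_food,24
Pizza Hut,fast_food,25
Pita Pit,fast_food,17
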