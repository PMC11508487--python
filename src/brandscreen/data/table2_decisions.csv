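sector,brand,permitted_25,permitted_50,permitted_75,permitted_90
packaged_food,Anchor,Y,Y,N,N
packaged_food,Arnott's,N,N,N,N
packaged_food,Bluebird,N,N,N,N
packaged_food,Cadbury,N,N,N,N
packaged_food,Eta,N,N,N,N
packaged_food,Flora,Y,Y,Y,Y
packaged_food,Fresh'n Fruity,Y,Y,N,N
packaged_food,Griffin's,N,N,N,N
packaged_food,Maggi,Y,N,N,N
packaged_food,Mainland,N,N,N,N
packaged_food,McCain,Y,Y,N,N
packaged_food,Meadow Fresh,Y,Y,N,N
packaged_food,Meadow Lea,Y,Y,Y,Y
packaged_food,Quality Bakers,Y,Y,Y,N
packaged_food,Sanitarium,N,N,N,N
packaged_food,Sealord,Y,Y,Y,Y
packaged_food,Tegel,Y,Y,Y,N
packaged_food,Tip Top,N,N,N,N
packaged_food,Wattie's,Y,Y,N,N
packaged_food,Whittaker's,N,N,N,N
beverage,Charlie's,N,N,N,N
beverage,Coca Cola,N,N,N,N
beverage,E2,N,N,N,N
beverage,Fresh Up,N,N,N,N
beverage,H2Go,N,N,N,N
beverage,Just Juice,N,N,N,N
beverage,Keri Juice Co,N,N,N,N
beverage,Kiwi Blue,Y,Y,Y,N
beverage,L&P,N,N,N,N
beverage,McCoy,N,N,N,N
beverage,Mizone,N,N,N,N
beverage,NZ Natural,Y,Y,Y,Y
beverage,Powerade,N,N,N,N
beverage,Pump,Y,Y,Y,Y
beverage,Pure Dew,Y,Y,Y,Y
beverage,Pure NZ,Y,Y,Y,Y
beverage,Red Bull,N,N,N,N
beverage,Schweppes,N,N,N,N
beverage,Sprite,N,N,N,N
beverage,V,N,N,N,N
fast_food,Burger Fuel,N,N,N,N
fast_food,Burger King,N,N,N,N
fast_food,Domino's Pizza,N,N,N,N
fast_food,Hell Pizza,N,N,N,N
fast_food,KFC,N,N,N,N
fast_food,McDonald's,N,N,N,N
fast_food,Pizza Hut,Y,N,N,N
fast_food,St Pierre's Sushi,Y,Y,N,N
fast_food,Subway,Y,Y,N,N
fast_food,Tank Juice,Y,N,N,N
fast_food,Wendy's,N,N,N,N
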