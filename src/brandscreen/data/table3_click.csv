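brand,permitted_50,permitted_75,leading_product,click_permitted
Anchor,Y,N,Probiotic Plus Strawberry and Raspberry Yoghurt,Y
Arnott's,N,N,Tim Tam Classic,N
Bluebird,N,N,Originals Ready Salted Chips,N
Cadbury,N,N,Dairy Milk,N
Eta,N,N,Ready Salted Ripples,N
Griffin's,N,N,Mallowpuffs Original,N
Flora,Y,Y,Flora Original,Y
Fresh'n Fruity,Y,N,Mixed Berry Yoghurt Six Pack,Y
Mainland,N,N,Grated Tasty Cheese,N
Maggi,N,N,Rich and Saucy Beef Casserole,N
McCain,Y,N,Pub Size Chicken Kiev,N
Meadow Fresh,Y,N,Original Milk,Y
Meadow Lea,Y,Y,Original Margarine,Y
Quality Bakers,Y,Y,Muffin Splits,Y
Sanitarium,N,N,Weetbix,Y
Sealord,Y,Y,New Zealand Hoki Fish Fingers Classic Crumb,Y
Tegel,Y,Y,Memphis BBQ Wraps,N
Tip Top,N,N,Pineapple Fruju,N
Wattie's,Y,N,Spaghetti in Tomato Sauce,Y
Whittaker's,N,N,Creamy Milk,N
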